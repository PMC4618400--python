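"""Run configuration, staged pipeline execution and JSON reporting.

A :class:`RunConfig` selects any combination of the four analysis stages
(Taylor g-value analysis, EPR mixture fit, optical band fit, pKa
inference) with their physical settings; :func:`run_pipeline` executes
them in order and returns a validated :class:`Report`.  The report
schema is shipped as ``report_schema.json`` next to this module so
downstream consumers can validate outputs without importing the package.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, PositiveFloat

from . import epr, ligand_field, optical
from .constants import ZETA_DEFAULT_CM
from .io import read_spectrum

__all__ = ["RunConfig", "Report", "run_pipeline", "report_schema", "write_report"]


class TaylorStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    g_magnitudes: tuple[PositiveFloat, PositiveFloat, PositiveFloat] | None = None
    g_signed: tuple[float, float, float] | None = None
    zeta_cm: PositiveFloat = ZETA_DEFAULT_CM


class EPRFitStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    observed_path: str
    component_paths: list[str] = Field(min_length=1)


class BandFitStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    abs_path: str
    mcd_path: str | None = None
    initial_bands: list[tuple[float, float, float]] = Field(min_length=1)
    labels: list[str] | None = None
    center_window_cm: PositiveFloat | None = 500.0
    fwhm_bounds_cm: tuple[PositiveFloat, PositiveFloat] = (800.0, 6000.0)
    temperature_K: PositiveFloat = 5.0
    field_T: PositiveFloat = 7.0


class PKaStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    points: list[tuple[float, float]] = Field(min_length=1)


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    taylor: TaylorStage | None = None
    epr_fit: EPRFitStage | None = None
    band_fit: BandFitStage | None = None
    pka: PKaStage | None = None
    seed: int = 0
    output_dir: str | None = None


class TaylorResult(BaseModel):
    g_signed: tuple[float, float, float]
    coefficients: tuple[float, float, float]
    coefficients_table_scaled: tuple[float, float, float]
    delta_cm: float
    v_abs_cm: float
    rhombicity: float
    trans1_cm: float
    trans2_cm: float
    residual: float | None = None


class MixtureReport(BaseModel):
    fractions: list[float]
    residual_norm: float


class BandRow(BaseModel):
    label: str
    energy_cm: float
    fwhm_cm: float
    epsilon: float
    delta_epsilon: float | None = None
    cd_ratio_x1e4: int | None = None


class PKaResult(BaseModel):
    pka: float
    rmse: float | None = None
    n_points: int


class Report(BaseModel):
    """Machine-readable pipeline output."""

    model_config = ConfigDict(extra="forbid")
    seed: int
    taylor: TaylorResult | None = None
    epr_fit: MixtureReport | None = None
    band_table: list[BandRow] | None = None
    pka: PKaResult | None = None


def _run_taylor(stage: TaylorStage) -> TaylorResult:
    if stage.g_signed is not None:
        g = ligand_field.SignedGTensor(*stage.g_signed)
        residual = None
    elif stage.g_magnitudes is not None:
        cands = ligand_field.assign_g_tensor(stage.g_magnitudes, zeta=stage.zeta_cm)
        g, residual = cands[0].g, cands[0].residual
    else:
        raise ValueError("taylor stage needs g_signed or g_magnitudes")
    coeffs = ligand_field.coefficients_from_g(g)
    params = ligand_field.ligand_field_from_g(g, zeta=stage.zeta_cm)
    trans = ligand_field.predicted_transitions(params)
    return TaylorResult(
        g_signed=(g.g_x, g.g_y, g.g_z),
        coefficients=(coeffs.a, coeffs.b, coeffs.c),
        coefficients_table_scaled=coeffs.table_scaled(),
        delta_cm=params.delta,
        v_abs_cm=abs(params.v),
        rhombicity=params.rhombicity,
        trans1_cm=trans.trans1,
        trans2_cm=trans.trans2,
        residual=residual,
    )


def _run_epr_fit(stage: EPRFitStage) -> MixtureReport:
    observed = read_spectrum(stage.observed_path, expected_mode="epr")
    comps = [
        read_spectrum(p, expected_mode="epr").resample(observed.field_mT)
        for p in stage.component_paths
    ]
    res = epr.fit_mixture(observed, comps)
    return MixtureReport(fractions=list(res.fractions), residual_norm=res.residual_norm)


def _run_band_fit(stage: BandFitStage) -> list[BandRow]:
    abs_spec = read_spectrum(stage.abs_path, expected_mode="absorption")
    init = [optical.GaussianBand(*b) for b in stage.initial_bands]
    abs_bands, _ = optical.fit_gaussian_bands(
        abs_spec, init, center_window=stage.center_window_cm,
        fwhm_bounds=stage.fwhm_bounds_cm,
    )
    labels = stage.labels or [chr(ord("a") + i) for i in range(len(abs_bands))]
    if stage.mcd_path is None:
        return [
            BandRow(label=l, energy_cm=b.center, fwhm_cm=b.fwhm, epsilon=b.amplitude)
            for l, b in zip(labels, abs_bands)
        ]
    mcd_spec = read_spectrum(stage.mcd_path, expected_mode="mcd")
    mcd_init = [
        optical.GaussianBand(b.center, b.fwhm, mi.amplitude)
        for b, mi in zip(abs_bands, init)
    ]
    mcd_bands, _ = optical.fit_gaussian_bands(
        mcd_spec, mcd_init, center_window=stage.center_window_cm,
        fwhm_bounds=stage.fwhm_bounds_cm,
    )
    table = optical.build_band_table(
        abs_bands, mcd_bands, labels,
        temperature_K=stage.temperature_K, field_T=stage.field_T,
    )
    return [
        BandRow(
            label=row.label,
            energy_cm=row.abs_band.center,
            fwhm_cm=row.abs_band.fwhm,
            epsilon=row.abs_band.amplitude,
            delta_epsilon=row.mcd_band.amplitude if row.mcd_band else None,
            cd_ratio_x1e4=row.cd_ratio_x1e4,
        )
        for row in table
    ]


def _run_pka(stage: PKaStage) -> PKaResult:
    if len(stage.points) == 1:
        ph, f = stage.points[0]
        return PKaResult(pka=epr.pka_single_point(ph, f), n_points=1)
    series = epr.TitrationSeries(points=tuple(stage.points))
    pka, diag = epr.pka_logistic_fit(series)
    return PKaResult(pka=pka, rmse=diag["rmse"], n_points=diag["n_points"])


def run_pipeline(config: RunConfig) -> Report:
    """Execute the configured stages; stage errors carry the stage name."""
    results: dict = {"seed": config.seed}
    for name, stage, runner in (
        ("taylor", config.taylor, _run_taylor),
        ("epr_fit", config.epr_fit, _run_epr_fit),
        ("band_fit", config.band_fit, _run_band_fit),
        ("pka", config.pka, _run_pka),
    ):
        if stage is None:
            continue
        try:
            out = runner(stage)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        results["band_table" if name == "band_fit" else name] = out
    report = Report(**results)
    if config.output_dir is not None:
        write_report(Path(config.output_dir) / "report.json", report)
    return report


def write_report(path: str | Path, report: Report) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(report.model_dump_json(indent=2) + "\n")


def report_schema() -> dict:
    """The shipped JSON schema for :class:`Report`."""
    with resources.files("lsferric").joinpath("report_schema.json").open() as fh:
        return json.load(fh)
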