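"""Gaussian band deconvolution of absorption/MCD pairs and C/D ratios.

Electronic spectra of metalloprotein sites are modelled as sums of
Gaussian bands on a wavenumber axis,

    I(v) = sum_i A_i exp(-4 ln2 (v - v_i)^2 / fwhm_i^2),

positive in absorption (A = epsilon at the maximum) and signed in MCD
(A = delta-epsilon).  For a paramagnet in the linear (Curie) regime the
MCD C-term to dipole-strength ratio of a band follows from its
delta-epsilon/epsilon ratio:

    |C/D| = (k_B T / (mu_B B)) * |delta_eps / eps|

conventionally tabulated as |C/D| x 1e4.  d-d transitions carry larger
C/D than charge-transfer bands, which is the main diagnostic use.  Two
oppositely-signed C-terms with large |C/D| flag a spin-orbit coupled
pseudo-A pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lmfit import Parameters, minimize

from .constants import KB_CM_PER_K, MUB_CM_PER_T
from .spectra import OpticalSpectrum

__all__ = [
    "GaussianBand",
    "BandAssignment",
    "gaussian_profile",
    "model_spectrum",
    "fit_gaussian_bands",
    "cd_ratio",
    "cd_ratio_x1e4",
    "build_band_table",
    "detect_pseudo_a",
]

_FOUR_LN2 = 4.0 * np.log(2.0)


@dataclass(frozen=True)
class GaussianBand:
    """A single Gaussian band: center (cm^-1), FWHM (cm^-1), peak amplitude."""

    center: float
    fwhm: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.center <= 0:
            raise ValueError("band center must be positive")
        if self.fwhm <= 0:
            raise ValueError("band FWHM must be positive")


@dataclass(frozen=True)
class BandAssignment:
    """A paired absorption/MCD band with its C/D ratio and a label.

    ``mcd_band`` is None (and ``cd_ratio`` undefined) for an unpaired
    absorption band; such rows are kept explicitly, never dropped.
    """

    label: str
    abs_band: GaussianBand
    mcd_band: GaussianBand | None
    cd_ratio: float | None
    assignment: str = ""

    @property
    def cd_ratio_x1e4(self) -> int | None:
        if self.cd_ratio is None:
            return None
        return int(np.floor(self.cd_ratio * 1e4 + 0.5))  # round half up


def gaussian_profile(energy_cm: np.ndarray, band: GaussianBand) -> np.ndarray:
    v = np.asarray(energy_cm, dtype=float)
    return band.amplitude * np.exp(-_FOUR_LN2 * (v - band.center) ** 2 / band.fwhm**2)


def model_spectrum(energy_cm: np.ndarray, bands: list[GaussianBand]) -> np.ndarray:
    """Pointwise sum of the component Gaussians."""
    out = np.zeros_like(np.asarray(energy_cm, dtype=float))
    for b in bands:
        out += gaussian_profile(energy_cm, b)
    return out


def fit_gaussian_bands(
    spectrum: OpticalSpectrum,
    initial: list[GaussianBand],
    center_window: float | None = None,
    fwhm_bounds: tuple[float, float] = (800.0, 6000.0),
    link_centers_to: list[GaussianBand] | None = None,
    share_fwhm: bool = False,
) -> tuple[list[GaussianBand], dict]:
    """Nonlinear least-squares sum-of-Gaussians fit.

    Parameters
    ----------
    initial : starting bands; centers must lie inside the grid.
    center_window : if given, each center is bounded to its initial
        value +/- this window (cm^-1).  Essential for heavily
        overlapped bands.
    fwhm_bounds : global (lower, upper) bounds on every FWHM.
    link_centers_to : fix centers to those of a previous fit (e.g. hold
        MCD centers at the absorption values).
    share_fwhm : constrain all bands to one common width.  Weak bands
        buried under strong neighbours are unidentifiable with fully
        free widths; a shared width is the usual deconvolution
        constraint when no band is resolved enough to fix its own.

    Returns the fitted bands sorted by center and a report dict with the
    residual norm and the lmfit result.
    """
    if not initial:
        raise ValueError("need at least one initial band")
    lo, hi = spectrum.energy_cm[0], spectrum.energy_cm[-1]
    for b in initial:
        if not (lo <= b.center <= hi):
            raise ValueError(f"initial center {b.center} outside grid [{lo}, {hi}]")
    centers = [b.center for b in initial]
    if len(set(np.round(centers, 6))) < len(centers):
        warnings.warn("identical initial centers; fit is ill-conditioned", stacklevel=2)

    params = Parameters()
    amp_sign_free = spectrum.mode == "mcd"
    for i, b in enumerate(initial):
        fixed_center = link_centers_to[i].center if link_centers_to else None
        params.add(
            f"c{i}",
            value=fixed_center if fixed_center is not None else b.center,
            vary=fixed_center is None,
            min=b.center - center_window if center_window else -np.inf,
            max=b.center + center_window if center_window else np.inf,
        )
        if share_fwhm and i > 0:
            params.add(f"w{i}", expr="w0")
        else:
            params.add(f"w{i}", value=b.fwhm, min=fwhm_bounds[0], max=fwhm_bounds[1])
        params.add(
            f"a{i}",
            value=b.amplitude,
            min=-np.inf if amp_sign_free else 0.0,
        )

    v = spectrum.energy_cm
    n = len(initial)

    def residual(p):
        model = np.zeros_like(v)
        for i in range(n):
            model += p[f"a{i}"] * np.exp(
                -_FOUR_LN2 * (v - p[f"c{i}"]) ** 2 / p[f"w{i}"] ** 2
            )
        return model - spectrum.intensity

    result = minimize(residual, params)
    fitted = [
        GaussianBand(
            center=float(result.params[f"c{i}"]),
            fwhm=float(result.params[f"w{i}"]),
            amplitude=float(result.params[f"a{i}"]),
        )
        for i in range(n)
    ]
    fitted.sort(key=lambda b: b.center)
    report = {
        "residual_norm": float(np.linalg.norm(result.residual)),
        "success": bool(result.success),
        "nfev": int(result.nfev),
        "lmfit_result": result,
    }
    if not result.success:
        report["message"] = result.message
    return fitted, report


def cd_ratio(
    eps: float, delta_eps: float, temperature_K: float, field_T: float
) -> float:
    """|C/D| of a band from its peak epsilon and delta-epsilon.

    Linear-regime (Curie) formula |C/D| = (k_B T / mu_B B) |d_eps/eps|;
    linear in delta_eps, inverse-linear in eps, hence invariant under a
    common rescaling of both.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if temperature_K <= 0 or field_T <= 0:
        raise ValueError("temperature and field must be positive")
    return (KB_CM_PER_K * temperature_K / (MUB_CM_PER_T * field_T)) * abs(
        delta_eps / eps
    )


def cd_ratio_x1e4(
    eps: float, delta_eps: float, temperature_K: float, field_T: float
) -> int:
    """Table convention: |C/D| x 1e4, rounded half-up to an integer."""
    return int(np.floor(cd_ratio(eps, delta_eps, temperature_K, field_T) * 1e4 + 0.5))


def build_band_table(
    abs_bands: list[GaussianBand],
    mcd_bands: list[GaussianBand],
    labels: list[str],
    temperature_K: float,
    field_T: float,
    assignments: list[str] | None = None,
    pairing_tolerance: float = 1500.0,
) -> list[BandAssignment]:
    """Pair absorption and MCD bands by nearest center and tabulate C/D.

    One row per absorption band: energy from the absorption fit, epsilon,
    signed delta-epsilon from the matched MCD band, and |C/D|.  An
    absorption band with no MCD partner within ``pairing_tolerance``
    cm^-1 becomes an explicit unpaired row.  Assignment labels are
    caller-supplied metadata (band assignments come from resonance Raman
    or computation, not from this analysis).
    """
    if len(labels) != len(abs_bands):
        raise ValueError("need one label per absorption band")
    if assignments is None:
        assignments = [""] * len(abs_bands)
    rows: list[BandAssignment] = []
    available = list(range(len(mcd_bands)))
    for label, ab, assign in zip(labels, sorted(abs_bands, key=lambda b: b.center), assignments):
        best, best_d = None, np.inf
        for j in available:
            d = abs(mcd_bands[j].center - ab.center)
            if d < best_d:
                best, best_d = j, d
        if best is None or best_d > pairing_tolerance:
            rows.append(BandAssignment(label, ab, None, None, assign))
            continue
        available.remove(best)
        mb = mcd_bands[best]
        rows.append(
            BandAssignment(
                label,
                ab,
                mb,
                cd_ratio(ab.amplitude, mb.amplitude, temperature_K, field_T),
                assign,
            )
        )
    return rows


def detect_pseudo_a(
    bands: list[BandAssignment], cd_threshold_x1e4: float = 200.0
) -> list[tuple[BandAssignment, BandAssignment]]:
    """Flag candidate pseudo-A pairs among assigned bands.

    A pseudo-A term arises from two spin-orbit-coupled, perpendicularly
    polarized transitions and shows as oppositely signed C-terms, both
    with substantial |C/D|.  Every pair of bands with opposite MCD signs
    and both |C/D| x 1e4 at or above the threshold is returned, nearest
    in energy first.  Polarization information is not available here, so
    these are candidates, not confirmations.
    """
    paired = [b for b in bands if b.mcd_band is not None]
    out = []
    for i in range(len(paired)):
        for j in range(i + 1, len(paired)):
            bi, bj = paired[i], paired[j]
            if bi.mcd_band.amplitude * bj.mcd_band.amplitude >= 0:
                continue
            if (
                bi.cd_ratio_x1e4 >= cd_threshold_x1e4
                and bj.cd_ratio_x1e4 >= cd_threshold_x1e4
            ):
                out.append((bi, bj))
    out.sort(key=lambda p: abs(p[0].abs_band.center - p[1].abs_band.center))
    return out
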