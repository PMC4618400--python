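"""Seeded synthetic-data generators emulating the pipeline's inputs.

No deposited spectra exist for the Fe(III) nitrile hydratase forms this
package targets, so every stage is exercised on synthetic data built
from the published spectroscopic parameters: rhombic S = 1/2 powder EPR
mixtures with Gaussian lines, single-ionization pH titrations, and
paired absorption/MCD sum-of-Gaussian spectra.  All generators are pure
functions of (parameters, seed); noise is additive white Gaussian with a
standard deviation given relative to the maximum absolute intensity.

The preset library hard-codes the published band parameters and g values
of the butyrate-bound (``NHaseBA``) and aqueous active (``NHaseAq``)
enzyme forms as the canonical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epr import EPRSpeciesModel, logistic_fraction, powder_pattern, TitrationSeries
from .exceptions import GridCoverageError
from .optical import GaussianBand, model_spectrum
from .spectra import EPRSpectrum, OpticalSpectrum

__all__ = [
    "SyntheticConfig",
    "make_epr_mixture",
    "make_titration_series",
    "make_optical_pair",
    "EPR_SPECIES_PRESETS",
    "OPTICAL_PRESETS",
    "optical_preset_bands",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Grid and noise settings shared by the generators."""

    seed: int = 0
    noise_sigma: float = 0.0  # relative to max |intensity|
    grid_start: float = 260.0
    grid_stop: float = 380.0
    grid_points: int = 1024

    def __post_init__(self) -> None:
        if self.grid_points < 50:
            raise ValueError("need at least 50 grid points")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    def grid(self) -> np.ndarray:
        return np.linspace(self.grid_start, self.grid_stop, self.grid_points)


# --- published EPR species of the enzyme forms (X-band, 77 K) -------------
EPR_SPECIES_PRESETS: dict[str, EPRSpeciesModel] = {
    # butyrate-bound form: clean single species
    "BA": EPRSpeciesModel("BA", (2.28, 2.14, 1.97)),
    # aqueous active form at pH 7.5: major species
    "Aq-major": EPRSpeciesModel("Aq-major", (2.20, 2.13, 1.99)),
    # minor species that grows toward high pH (aquo -> hydroxo ionization)
    "Aq-minor-high-pH": EPRSpeciesModel("Aq-minor-high-pH", (2.22, 2.14, 1.98)),
    # minor species that grows toward low pH (sulfenate protonation)
    "Aq-minor-low-pH": EPRSpeciesModel("Aq-minor-low-pH", (2.28, 2.14, 1.97)),
}


def make_epr_mixture(
    models: list[EPRSpeciesModel],
    fractions: list[float],
    frequency_GHz: float = 9.40,
    config: SyntheticConfig = SyntheticConfig(),
    n_theta: int = 200,
    n_phi: int = 200,
    components: list[EPRSpectrum] | None = None,
) -> EPRSpectrum:
    """Noisy weighted sum of powder patterns.

    ``components`` may carry pre-simulated noiseless patterns for the
    same models/grid to avoid re-running the orientation average when
    only the seed changes.
    """
    if len(models) != len(fractions):
        raise ValueError("one fraction per species model required")
    frac = np.asarray(fractions, dtype=float)
    if np.any(frac < 0) or abs(frac.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be non-negative and sum to 1")
    grid = config.grid()
    if components is None:
        components = [
            powder_pattern(m, grid, frequency_GHz, n_theta=n_theta, n_phi=n_phi)
            for m in models
        ]
    clean = np.zeros_like(grid)
    for f, c in zip(frac, components):
        clean += f * c.intensity
    rng = np.random.default_rng(config.seed)
    noisy = clean + rng.normal(
        0.0, config.noise_sigma * np.max(np.abs(clean)), size=clean.shape
    )
    return EPRSpectrum(
        field_mT=grid,
        intensity=noisy,
        microwave_frequency_GHz=frequency_GHz,
        label="synthetic mixture: " + " + ".join(m.name for m in models),
    )


def make_titration_series(
    pka: float,
    ph_values: list[float],
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> TitrationSeries:
    """Single-ionization titration fractions with clipped Gaussian noise."""
    if not ph_values:
        raise ValueError("pH list must be nonempty")
    rng = np.random.default_rng(seed)
    pts = []
    for ph in ph_values:
        f = logistic_fraction(ph, pka) + rng.normal(0.0, noise_sigma)
        pts.append((float(ph), float(np.clip(f, 0.0, 1.0))))
    return TitrationSeries(points=tuple(pts))


# --- published UV-Vis band parameters (5 K absorption; 5 K / 7 T MCD) -----
# per band: (center cm^-1, peak epsilon M^-1 cm^-1, peak delta-epsilon)
_BA_BANDS = [
    ("a", 13600.0, 1250.0, 36.0),
    ("b", 15700.0, 500.0, 10.0),
    ("c", 17500.0, 350.0, 2.0),
    ("d", 19500.0, 760.0, 38.0),
    ("e", 21800.0, 1060.0, 14.0),
    ("f", 24700.0, 2050.0, -59.0),
    ("g", 27000.0, 2200.0, -3.0),
    ("h", 30000.0, 3350.0, -14.0),
]
_AQ_BANDS = [
    ("a", 14300.0, 1200.0, 54.0),
    ("b", 16900.0, 310.0, -4.0),
    ("c", 20100.0, 450.0, 16.0),
    ("d", 21700.0, 780.0, 16.0),
    ("e", 23900.0, 1000.0, -9.0),
    ("f", 27500.0, 3180.0, -32.0),
    ("g", 30600.0, 2890.0, -13.0),
]
OPTICAL_PRESETS: dict[str, list[tuple[str, float, float, float]]] = {
    "NHaseBA": _BA_BANDS,
    "NHaseAq": _AQ_BANDS,
}
DEFAULT_BAND_FWHM = 2500.0  # cm^-1; band widths are not published


def optical_preset_bands(
    name: str, fwhm: float = DEFAULT_BAND_FWHM
) -> tuple[list[str], list[GaussianBand], list[GaussianBand]]:
    """Labels, absorption bands and MCD bands for a named preset."""
    rows = OPTICAL_PRESETS[name]
    labels = [r[0] for r in rows]
    abs_bands = [GaussianBand(r[1], fwhm, r[2]) for r in rows]
    mcd_bands = [GaussianBand(r[1], fwhm, r[3]) for r in rows]
    return labels, abs_bands, mcd_bands


def make_optical_pair(
    abs_bands: list[GaussianBand],
    mcd_bands: list[GaussianBand],
    energy_grid: np.ndarray,
    noise_sigma: float = 0.0,
    seed: int = 0,
    temperature_K: float = 5.0,
    field_T: float = 7.0,
) -> tuple[OpticalSpectrum, OpticalSpectrum]:
    """Paired absorption/MCD sum-of-Gaussians spectra with noise."""
    if not abs_bands or not mcd_bands:
        raise ValueError("band lists must be nonempty")
    grid = np.asarray(energy_grid, dtype=float)
    for b in abs_bands + mcd_bands:
        if b.center - 2 * b.fwhm < grid[0] or b.center + 2 * b.fwhm > grid[-1]:
            raise GridCoverageError(
                f"grid does not cover band at {b.center} cm^-1 +/- 2 FWHM"
            )
    rng = np.random.default_rng(seed)
    out = []
    for bands, mode in ((abs_bands, "absorption"), (mcd_bands, "mcd")):
        clean = model_spectrum(grid, bands)
        noisy = clean + rng.normal(
            0.0, noise_sigma * np.max(np.abs(clean)), size=grid.shape
        )
        if mode == "absorption":
            noisy = np.clip(noisy, 0.0, None)
        out.append(
            OpticalSpectrum(
                energy_cm=grid,
                intensity=noisy,
                mode=mode,
                temperature_K=temperature_K,
                magnetic_field_T=field_T,
                label="synthetic",
            )
        )
    return out[0], out[1]
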