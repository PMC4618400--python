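"""Powder EPR simulation, mixture quantitation and pKa inference.

A frozen-solution S = 1/2 sample contains randomly oriented molecules.
For a rhombic g tensor the effective g along a direction with polar
angles (theta, phi) in the molecular frame is

    g_eff = sqrt(g_x^2 sin^2(th) cos^2(ph)
               + g_y^2 sin^2(th) sin^2(ph) + g_z^2 cos^2(th))

and each orientation resonates at B = (h/mu_B) nu / g_eff.  Averaging
Gaussian lines over the sphere yields the powder pattern, whose field
derivative is what a field-modulated spectrometer records, with turning
points near the three principal g values.

Species quantitation is linear unmixing: each candidate component is
simulated with its underlying absorption area normalized to 1, so
non-negative least-squares amplitudes are proportional to populations.
pH-dependent populations of protonated/deprotonated forms follow a
single-ionization Henderson-Hasselbalch curve, inverted either from one
(pH, fraction) point or by least squares over a titration series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, nnls

from .constants import H_OVER_MUB_MT_GHZ
from .exceptions import GridCoverageError
from .spectra import EPRSpectrum

__all__ = [
    "EPRSpeciesModel",
    "MixtureResult",
    "TitrationSeries",
    "resonance_field",
    "powder_pattern",
    "fit_mixture",
    "pka_single_point",
    "pka_logistic_fit",
    "logistic_fraction",
]

_FOUR_LN2 = 4.0 * np.log(2.0)


@dataclass(frozen=True)
class EPRSpeciesModel:
    """A rhombic S=1/2 species: |g| triple and per-axis Gaussian FWHM (mT)."""

    name: str
    g_magnitudes: tuple[float, float, float]
    linewidths_mT: tuple[float, float, float] = (1.5, 1.5, 1.5)

    def __post_init__(self) -> None:
        if any(not (0 < g < 4) for g in self.g_magnitudes):
            raise ValueError("g magnitudes must lie in (0, 4)")
        if any(w <= 0 for w in self.linewidths_mT):
            raise ValueError("linewidths must be positive")


@dataclass(frozen=True)
class MixtureResult:
    """Non-negative species fractions (sum to 1) and the fit residual norm."""

    fractions: tuple[float, ...]
    residual_norm: float

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be non-negative")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


@dataclass(frozen=True)
class TitrationSeries:
    """(pH, fraction_protonated) observations of a single ionization."""

    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        for ph, f in self.points:
            if not np.isfinite(ph):
                raise ValueError("pH must be finite")
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"fraction {f} outside [0, 1]")


def resonance_field(g: float, frequency_GHz: float) -> float:
    """Resonance field in mT: B = (h/mu_B) * nu / g."""
    if g <= 0 or frequency_GHz <= 0:
        raise ValueError("g and frequency must be positive")
    return H_OVER_MUB_MT_GHZ * frequency_GHz / g


def _orientation_grid(n_theta: int, n_phi: int):
    """Equal-area midpoint grid over one octant (rhombic symmetry)."""
    cos_th = (np.arange(n_theta) + 0.5) / n_theta
    phi = (np.arange(n_phi) + 0.5) * (np.pi / 2) / n_phi
    ct, ph = np.meshgrid(cos_th, phi, indexing="ij")
    st = np.sqrt(1.0 - ct**2)
    # direction cosines, flattened
    lx = (st * np.cos(ph)).ravel()
    ly = (st * np.sin(ph)).ravel()
    lz = ct.ravel()
    return lx, ly, lz


def powder_pattern(
    model: EPRSpeciesModel,
    field_mT: np.ndarray,
    frequency_GHz: float = 9.40,
    n_theta: int = 200,
    n_phi: int = 200,
    derivative: bool = True,
    temperature_K: float = 77.0,
) -> EPRSpectrum:
    """Orientation-averaged powder spectrum of one rhombic species.

    Every orientation contributes a unit-area Gaussian at its resonance
    field with FWHM interpolated between the per-axis widths as
    sqrt(sum w_i^2 l_i^2); the underlying absorption integrates to 1
    before differentiation, so amplitudes of different species are
    directly comparable as populations.
    """
    grid = np.asarray(field_mT, dtype=float)
    g = np.asarray(model.g_magnitudes, dtype=float)
    b_lo = 0.9 * resonance_field(g.max(), frequency_GHz)
    b_hi = 1.1 * resonance_field(g.min(), frequency_GHz)
    if grid[0] > b_lo or grid[-1] < b_hi:
        raise GridCoverageError(
            f"field grid [{grid[0]:.1f}, {grid[-1]:.1f}] mT does not cover "
            f"[{b_lo:.1f}, {b_hi:.1f}] mT around the turning points"
        )

    lx, ly, lz = _orientation_grid(n_theta, n_phi)
    g_eff = np.sqrt(g[0] ** 2 * lx**2 + g[1] ** 2 * ly**2 + g[2] ** 2 * lz**2)
    b_res = H_OVER_MUB_MT_GHZ * frequency_GHz / g_eff
    w = np.asarray(model.linewidths_mT, dtype=float)
    fwhm = np.sqrt(w[0] ** 2 * lx**2 + w[1] ** 2 * ly**2 + w[2] ** 2 * lz**2)
    weight = 1.0 / b_res.size  # equal-area grid: uniform solid-angle weights

    out = np.zeros_like(grid)
    # chunk the orientation loop to bound peak memory
    for start in range(0, b_res.size, 4000):
        sl = slice(start, start + 4000)
        db = grid[None, :] - b_res[sl, None]
        s2 = fwhm[sl, None] ** 2 / _FOUR_LN2  # 2*sigma^2
        prof = np.exp(-(db**2) / s2) / np.sqrt(np.pi * s2)
        if derivative:
            prof *= -2.0 * db / s2
        out += weight * prof.sum(axis=0)
    return EPRSpectrum(
        field_mT=grid,
        intensity=out,
        microwave_frequency_GHz=frequency_GHz,
        temperature_K=temperature_K,
        label=model.name,
    )


def fit_mixture(observed: EPRSpectrum, components: list[EPRSpectrum]) -> MixtureResult:
    """Decompose a spectrum into non-negative fractions of components.

    All spectra must share the observed grid (resample first).  Because
    components are area-normalized simulations, the NNLS amplitudes are
    proportional to populations; they are renormalized to fractions.
    """
    if not components:
        raise ValueError("need at least one component")
    for c in components:
        if c.field_mT.shape != observed.field_mT.shape or not np.allclose(
            c.field_mT, observed.field_mT
        ):
            raise ValueError("component grids differ from the observed grid; resample")
    a = np.column_stack([c.intensity for c in components])
    if len(components) > 1:
        # warn on near-collinear component pairs
        norm = a / np.linalg.norm(a, axis=0, keepdims=True)
        gram = norm.T @ norm
        iu = np.triu_indices(len(components), k=1)
        if np.any(np.abs(gram[iu]) > 0.9999):
            warnings.warn(
                "component spectra are nearly collinear; fractions are "
                "poorly conditioned",
                stacklevel=2,
            )
    amps, rnorm = nnls(a, observed.intensity)
    total = amps.sum()
    if total == 0:
        raise ValueError("all fitted amplitudes are zero; components do not match data")
    return MixtureResult(fractions=tuple(amps / total), residual_norm=float(rnorm))


def logistic_fraction(ph: np.ndarray | float, pka: float) -> np.ndarray | float:
    """Protonated fraction of a single ionization: 1 / (1 + 10^(pH - pKa))."""
    return 1.0 / (1.0 + 10.0 ** (np.asarray(ph, dtype=float) - pka))


def pka_single_point(ph: float, fraction_protonated: float) -> float:
    """Henderson-Hasselbalch inversion from one titration point.

    pKa = pH + log10(f / (1 - f)); exact inverse of the logistic, so it
    is undefined at the endpoints f = 0 or 1.
    """
    if not (0.0 < fraction_protonated < 1.0):
        raise ValueError("fraction_protonated must lie strictly inside (0, 1)")
    return ph + np.log10(fraction_protonated / (1.0 - fraction_protonated))


def pka_logistic_fit(series: TitrationSeries) -> tuple[float, dict]:
    """Least-squares pKa from a multi-point titration series.

    Fits fraction(pH) = 1/(1 + 10^(pH - pKa)).  Warns when every point
    sits on one side of half-protonation within a narrow pH span — the
    plateau regions carry almost no information about pKa.
    """
    pts = [(ph, f) for ph, f in series.points if 0.0 < f < 1.0]
    if len(pts) < 2:
        raise ValueError("need at least two points with fractions strictly in (0, 1)")
    ph = np.array([p for p, _ in pts])
    frac = np.array([f for _, f in pts])
    if (np.all(frac > 0.5) or np.all(frac < 0.5)) and np.ptp(ph) < 0.5:
        warnings.warn(
            "titration points all on one side of pH = pKa over a span "
            "< 0.5 units; the fit is ill-conditioned",
            stacklevel=2,
        )
    p0 = np.median(ph + np.log10(frac / (1 - frac)))
    sol = least_squares(lambda p: logistic_fraction(ph, p[0]) - frac, x0=[p0])
    residuals = logistic_fraction(ph, sol.x[0]) - frac
    diagnostics = {
        "residuals": residuals,
        "rmse": float(np.sqrt(np.mean(residuals**2))),
        "n_points": len(pts),
        "success": bool(sol.success),
    }
    return float(sol.x[0]), diagnostics
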