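"""Gridded spectrum containers with acquisition metadata.

Two containers cover the pipeline: :class:`EPRSpectrum` (magnetic field
in mT vs first-derivative intensity) and :class:`OpticalSpectrum`
(wavenumber in cm^-1 vs molar intensity, absorption or MCD mode).  Both
validate their grids on construction and resample by linear
interpolation only — extrapolation is forbidden.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import GridCoverageError, MissingMetadataError

__all__ = ["EPRSpectrum", "OpticalSpectrum", "wavenumber_from_nm"]


def _validate_grid(grid: np.ndarray, values: np.ndarray, uniform: bool) -> None:
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("grid must be a 1-D array with at least 2 points")
    if grid.size != values.size:
        raise ValueError("grid and intensity lengths differ")
    d = np.diff(grid)
    if np.any(d <= 0):
        raise ValueError("grid must be strictly ascending")
    if uniform and (d.max() - d.min()) > 1e-9 * abs(d.mean()):
        raise ValueError("grid must be uniform to 1e-9 relative")


@dataclass(frozen=True)
class EPRSpectrum:
    """First-derivative X-band powder spectrum on a uniform field grid."""

    field_mT: np.ndarray
    intensity: np.ndarray
    microwave_frequency_GHz: float
    temperature_K: float = 77.0
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "field_mT", np.asarray(self.field_mT, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        _validate_grid(self.field_mT, self.intensity, uniform=True)
        if self.microwave_frequency_GHz <= 0:
            raise ValueError("microwave frequency must be positive")

    def resample(self, field_mT: np.ndarray) -> "EPRSpectrum":
        """Linear interpolation onto a new grid; must lie inside the old one."""
        new = np.asarray(field_mT, dtype=float)
        if new.min() < self.field_mT[0] or new.max() > self.field_mT[-1]:
            raise GridCoverageError("resampling grid extends beyond the data")
        return replace(self, field_mT=new, intensity=np.interp(new, self.field_mT, self.intensity))


@dataclass(frozen=True)
class OpticalSpectrum:
    """Absorption (epsilon) or MCD (delta-epsilon) spectrum vs wavenumber.

    MCD spectra must carry temperature and applied field; absorption
    intensities must be non-negative.
    """

    energy_cm: np.ndarray
    intensity: np.ndarray
    mode: str  # "absorption" | "mcd"
    temperature_K: float | None = None
    magnetic_field_T: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "energy_cm", np.asarray(self.energy_cm, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.mode not in ("absorption", "mcd"):
            raise ValueError(f"mode must be 'absorption' or 'mcd', got {self.mode!r}")
        _validate_grid(self.energy_cm, self.intensity, uniform=False)
        if self.mode == "mcd":
            if self.temperature_K is None or self.magnetic_field_T is None:
                raise MissingMetadataError(
                    "MCD spectra require temperature_K and magnetic_field_T"
                )
            if self.temperature_K <= 0 or self.magnetic_field_T <= 0:
                raise ValueError("temperature and field must be positive")

    def resample(self, energy_cm: np.ndarray) -> "OpticalSpectrum":
        new = np.asarray(energy_cm, dtype=float)
        if new.min() < self.energy_cm[0] or new.max() > self.energy_cm[-1]:
            raise GridCoverageError("resampling grid extends beyond the data")
        return replace(
            self, energy_cm=new, intensity=np.interp(new, self.energy_cm, self.intensity)
        )


def wavenumber_from_nm(nm: np.ndarray | float) -> np.ndarray | float:
    """Convert wavelength in nm to wavenumber in cm^-1 (1e7 / nm)."""
    return 1e7 / np.asarray(nm, dtype=float) if np.ndim(nm) else 1e7 / nm
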