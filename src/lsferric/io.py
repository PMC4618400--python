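"""Two-column delimited-text spectrum files with '#' header metadata.

Format: any number of leading ``# key = value`` comment lines, then two
whitespace-delimited numeric columns.  Recognized keys: ``kind``
(epr|absorption|mcd), ``frequency_GHz``, ``temperature_K``, ``field_T``,
``label``.  Descending grids are sorted ascending on read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .exceptions import MissingMetadataError, SpectrumFormatError
from .spectra import EPRSpectrum, OpticalSpectrum

__all__ = ["read_spectrum", "write_spectrum"]


def write_spectrum(path: str | Path, spectrum: EPRSpectrum | OpticalSpectrum) -> None:
    path = Path(path)
    lines = []
    if isinstance(spectrum, EPRSpectrum):
        lines += [
            "# kind = epr",
            f"# frequency_GHz = {spectrum.microwave_frequency_GHz!r}",
            f"# temperature_K = {spectrum.temperature_K!r}",
        ]
        x, y = spectrum.field_mT, spectrum.intensity
    else:
        lines.append(f"# kind = {spectrum.mode}")
        if spectrum.temperature_K is not None:
            lines.append(f"# temperature_K = {spectrum.temperature_K!r}")
        if spectrum.magnetic_field_T is not None:
            lines.append(f"# field_T = {spectrum.magnetic_field_T!r}")
        x, y = spectrum.energy_cm, spectrum.intensity
    if spectrum.label:
        lines.append(f"# label = {spectrum.label}")
    body = "\n".join(f"{float(xi)!r} {float(yi)!r}" for xi, yi in zip(x, y))
    path.write_text("\n".join(lines) + "\n" + body + "\n")


def _parse(path: Path) -> tuple[dict[str, str], np.ndarray, np.ndarray]:
    meta: dict[str, str] = {}
    xs, ys = [], []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" in line:
                key, _, value = line.lstrip("#").partition("=")
                meta[key.strip()] = value.strip()
            continue
        parts = line.split()
        if len(parts) != 2:
            raise SpectrumFormatError(
                f"{path}:{lineno}: expected two columns, got {len(parts)}"
            )
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError as exc:
            raise SpectrumFormatError(f"{path}:{lineno}: non-numeric row: {line!r}") from exc
    if len(xs) < 2:
        raise SpectrumFormatError(f"{path}: fewer than two data rows")
    x, y = np.array(xs), np.array(ys)
    order = np.argsort(x)
    return meta, x[order], y[order]


def read_spectrum(
    path: str | Path, expected_mode: str | None = None
) -> EPRSpectrum | OpticalSpectrum:
    """Read and validate a spectrum file; type dispatched on the header.

    ``expected_mode`` (epr|absorption|mcd) cross-checks the header and
    supplies the kind when the header omits it.
    """
    path = Path(path)
    meta, x, y = _parse(path)
    kind = meta.get("kind", expected_mode)
    if kind is None:
        raise MissingMetadataError(f"{path}: no 'kind' header and no expected_mode given")
    if expected_mode is not None and kind != expected_mode:
        raise SpectrumFormatError(
            f"{path}: header kind {kind!r} != expected {expected_mode!r}"
        )
    label = meta.get("label", "")
    if kind == "epr":
        if "frequency_GHz" not in meta:
            raise MissingMetadataError(f"{path}: EPR spectrum lacks 'frequency_GHz'")
        return EPRSpectrum(
            field_mT=x,
            intensity=y,
            microwave_frequency_GHz=float(meta["frequency_GHz"]),
            temperature_K=float(meta.get("temperature_K", 77.0)),
            label=label,
        )
    if kind in ("absorption", "mcd"):
        if kind == "mcd":
            for key in ("temperature_K", "field_T"):
                if key not in meta:
                    raise MissingMetadataError(f"{path}: MCD spectrum lacks {key!r}")
        return OpticalSpectrum(
            energy_cm=x,
            intensity=y,
            mode=kind,
            temperature_K=float(meta["temperature_K"]) if "temperature_K" in meta else None,
            magnetic_field_T=float(meta["field_T"]) if "field_T" in meta else None,
            label=label,
        )
    raise SpectrumFormatError(f"{path}: unknown kind {kind!r}")
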