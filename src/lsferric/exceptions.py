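"""Structured exceptions raised across the package."""


class LsFerricError(Exception):
    """Base class for all package errors."""


class NormalizationError(LsFerricError):
    """Hole coefficients are not normalized to unit length."""


class DegenerateAssignmentError(LsFerricError):
    """g values are degenerate; the Taylor inversion is undefined."""


class OrderingError(LsFerricError):
    """Ligand-field parameters violate |Delta| >= |V|/2."""


class GridCoverageError(LsFerricError):
    """Simulation or fit grid does not cover the required range."""


class SpectrumFormatError(LsFerricError):
    """A spectrum file could not be parsed."""


class MissingMetadataError(SpectrumFormatError):
    """Mandatory acquisition metadata absent from a spectrum header."""
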