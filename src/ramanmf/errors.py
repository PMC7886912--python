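"""Exception hierarchy.

Each failure mode named in the public API contracts raises a distinct
subclass of :class:`RamanMFError` so callers can discriminate without
string matching.
"""


class RamanMFError(Exception):
    """Base class for all package errors."""


class AxisError(RamanMFError):
    """Wavenumber axis is invalid (non-monotone, non-finite, too short)."""


class AxisMismatchError(RamanMFError):
    """Two objects that must share a wavenumber axis do not."""


class CoverageError(RamanMFError):
    """A spectrum does not cover the target axis (extrapolation needed)."""


class MetadataError(RamanMFError):
    """Metadata table malformed: row-count mismatch or missing column."""


class StageError(RamanMFError):
    """Operation applied to a spectrum in the wrong processing stage."""


class SpectrumError(RamanMFError):
    """Per-spectrum processing failure; carries the spectrum identifier."""

    def __init__(self, message: str, spectrum_id=None):
        super().__init__(message)
        self.spectrum_id = spectrum_id


class DuplicateNameError(RamanMFError):
    """Basis library names must be unique."""


class DegenerateSpectrumError(RamanMFError):
    """All-zero (or all-negative) spectrum cannot be area-normalized."""


class ConstantScoreError(RamanMFError):
    """Zero-variance score column where a correlation was requested."""


class MissingControlError(RamanMFError):
    """No 0 Gy control group for a (cell_line, day) comparison."""


class UnmappedCellLineError(RamanMFError):
    """A cell line in the data has no radio-sensitivity class mapping."""


class ConfigError(RamanMFError):
    """Pipeline configuration failed schema validation."""
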