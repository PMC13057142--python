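"""Exception hierarchy for mirqc.

Every error raised by the library derives from :class:`MirqcError`, so callers
(and the CLI) can distinguish domain failures from programming errors.
"""


class MirqcError(Exception):
    """Base class for all mirqc errors."""


class ParseError(MirqcError):
    """A spectrum file could not be parsed (names the offending column/row)."""


class OutOfRangeError(MirqcError):
    """A wavenumber lies outside the spectral range of a spectrum."""


class EmptyRegionError(MirqcError):
    """A requested wavenumber interval does not overlap the spectrum."""


class CoverageError(MirqcError):
    """A spectrum does not cover a wavenumber range required by an indicator."""


class DegenerateSpectrumError(MirqcError):
    """A spectrum is degenerate for the requested operation (e.g. zero area)."""


class DegenerateReferenceError(MirqcError):
    """A background pair carries no usable gas signal (near-identical scans)."""


class AnchorError(MirqcError):
    """The anchor-wavenumber intensity is unusable (non-positive)."""


class FitError(MirqcError):
    """A regression could not be fitted (e.g. zero-variance regressor)."""


class DomainError(MirqcError):
    """Intensity values are outside the mathematical domain of an operation."""
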