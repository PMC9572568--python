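"""Exception hierarchy shared across the package."""


class SpikedSpecError(Exception):
    """Base class for all package-specific errors."""


class SpectraFormatError(SpikedSpecError):
    """A file is structurally not a valid spectra table (e.g. missing column)."""


class SpectraParseError(SpikedSpecError):
    """A cell of a spectra file could not be parsed as a number."""


class SpectraValidationError(SpikedSpecError, ValueError):
    """A SpectraSet violates one of its invariants."""


class DimensionMismatchError(SpikedSpecError, ValueError):
    """Arrays that must share a grid or a length do not."""


class ParameterError(SpikedSpecError, ValueError):
    """An algorithm parameter is out of its admissible range."""


class DegenerateInputError(SpikedSpecError, ValueError):
    """Input is too small or too degenerate for the requested operation."""


class ZeroVarianceError(DegenerateInputError):
    """A row/response with zero variance where variance is required."""


class RankError(SpikedSpecError, ValueError):
    """More latent variables requested than the data can support."""


class NotFittedError(SpikedSpecError, RuntimeError):
    """A transform or model was applied before being fitted."""
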