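"""Exception types shared across the pipeline."""


class AnsmapError(Exception):
    """Base class for all package-specific errors."""


class SeriesTooShortError(AnsmapError, ValueError):
    """Beat series shorter than the minimum needed for spectral analysis."""


class DegenerateInputError(AnsmapError, ValueError):
    """Input is numerically degenerate (zero variance, empty band, ...)."""


class StageError(AnsmapError, RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""
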