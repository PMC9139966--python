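"""Exception types shared across the pipeline."""


class NoDecayError(ValueError):
    """Raised when a chase series shows no measurable decay (zero slope)."""


class DegenerateSeparationError(ValueError):
    """Raised when positive and negative screen controls have equal means."""


class StackFormatError(ValueError):
    """Raised when an image stack on disk is not a (frame, channel, y, x) TIFF."""


class PipelineDependencyError(RuntimeError):
    """Raised when a pipeline stage is missing an upstream stage's output."""
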