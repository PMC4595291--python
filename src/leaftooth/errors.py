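"""Exception hierarchy for the leaftooth pipeline."""


class LeafToothError(Exception):
    """Base class for all leaftooth errors."""


class InputError(LeafToothError):
    """Malformed or unsupported input (bad channel count, missing file, ...)."""


class DegenerateInputError(InputError):
    """Input is formally valid but carries no usable signal (constant image, ...)."""


class ExtractionError(LeafToothError):
    """A pipeline stage failed to produce its output on this image."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class GeometryError(LeafToothError):
    """Degenerate polygon/triangle geometry (coincident vertices, zero area)."""


class DegenerateToothError(GeometryError):
    """Tooth triangle is collapsed (zero-length edge or zero area)."""


class SolverError(LeafToothError):
    """The lasso solver failed to converge within its iteration budget."""


class ModelFormatError(LeafToothError):
    """A serialized model file is unreadable or has an unknown schema version."""
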