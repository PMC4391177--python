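"""Exception hierarchy for the toolbox."""


class CartBoxError(Exception):
    """Base class for all toolbox errors."""


class InvalidInputError(CartBoxError):
    """Malformed or non-finite input data."""


class InsufficientDataError(CartBoxError):
    """Too few usable points/landmarks for the requested operation."""


class DegenerateConfigurationError(CartBoxError):
    """Landmark set is collinear or coincident; no unique rigid fit exists."""


class UnsupportedTopologyError(CartBoxError):
    """Mesh topology outside the supported class (e.g. multiple basal rims)."""


class PipelineStageError(CartBoxError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
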