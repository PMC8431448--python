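"""Exception hierarchy shared across the package."""


class MolstackError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MolstackError):
    """A configuration or topology file violates the expected schema."""


class TopologyValidationError(MolstackError):
    """A topology is structurally invalid (masses, roles, ring sets)."""


class TrajectoryFormatError(MolstackError):
    """A trajectory file cannot be parsed.

    ``frame_index`` points at the offending frame; ``partial_frames``
    holds the frames that parsed cleanly before the failure.
    """

    def __init__(self, message, frame_index=None, partial_frames=None):
        super().__init__(message)
        self.frame_index = frame_index
        self.partial_frames = partial_frames or []


class GeometryError(MolstackError):
    """Degenerate geometry (collinear ring, zero vector, zero mass)."""


class GenerationError(MolstackError):
    """The synthetic generator could not realise the requested config."""
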