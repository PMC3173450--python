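"""Exception hierarchy shared by all srcensus modules."""


class SrcensusError(Exception):
    """Base class for all srcensus errors."""


class FormatError(SrcensusError):
    """A file or record violates its external format contract."""


class ConsistencyError(SrcensusError):
    """Inputs are individually well-formed but mutually contradictory."""


class AlignmentShapeError(FormatError):
    """A multiple alignment has ragged rows."""


class GenerationError(SrcensusError):
    """A synthetic-data configuration cannot host the requested structure."""
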