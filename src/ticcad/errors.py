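"""Exception hierarchy for ticcad."""


class TiccadError(Exception):
    """Base class for all ticcad errors."""


class FormatError(TiccadError):
    """An input file or object violates a structural invariant."""


class EmptyRoiError(TiccadError):
    """A ROI polygon covers no pixel centers."""


class DegenerateInputError(TiccadError):
    """An operation received input with no usable contrast (e.g. constant ROI)."""


class EmptySegmentationError(TiccadError):
    """The segmentation pipeline produced an empty mask."""


class PipelineError(TiccadError):
    """Every case in a pipeline run failed."""
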