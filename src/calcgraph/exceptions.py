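"""Exception hierarchy for calcgraph."""


class CalcgraphError(Exception):
    """Base class for all calcgraph errors."""


class FormatError(CalcgraphError):
    """Unreadable or unsupported image/annotation input."""


class ConfigurationError(CalcgraphError):
    """Invalid configuration value."""


class DegenerateInputError(CalcgraphError):
    """Input on which the requested operation is mathematically undefined."""


class DegenerateLabelError(CalcgraphError):
    """Training set lacks the label diversity the loss requires."""


class NoCalcificationsError(CalcgraphError):
    """An image yielded zero calcification candidates and cannot be classified."""


class StratificationError(CalcgraphError):
    """A class has too few members for the requested stratified split."""


class ShapeError(CalcgraphError):
    """Array dimensions incompatible with the model or operation."""


class ProvenanceError(CalcgraphError):
    """Artifacts passed together do not originate from the same image."""
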