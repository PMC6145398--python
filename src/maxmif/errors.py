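"""Exception hierarchy shared across the package."""


class MaxMIFError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MaxMIFError):
    """An input file violates the expected format (bad column, non-binary cell, ...)."""


class EmptyDataError(MaxMIFError):
    """An input contains no usable records (e.g. zero retained mutations)."""


class AbsentEdgeError(MaxMIFError):
    """A pairwise query was made for a gene pair that is not an edge of the network."""


class DegenerateInputError(MaxMIFError):
    """An evaluation input is degenerate (single class, zero-variance comparison, ...)."""
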