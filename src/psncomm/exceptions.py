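"""Exception hierarchy for psncomm.

All errors raised by the library derive from :class:`PsncommError` so callers
can catch library failures with a single except clause; the subclasses mirror
the distinct failure modes of the pipeline stages.
"""


class PsncommError(Exception):
    """Base class for all psncomm errors."""


class InvalidArgumentError(PsncommError, ValueError):
    """A precondition on an operation's arguments was violated."""


class FormatError(PsncommError):
    """An input file does not conform to its declared format."""


class SelectionError(PsncommError):
    """An atom-selection policy could not be resolved for some residue."""


class NormalizationError(PsncommError):
    """A normalization table is missing a residue type present in the data."""


class NoTransitionError(PsncommError):
    """An I_min scan profile is flat: no largest-cluster transition exists."""
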