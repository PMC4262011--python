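"""Exception hierarchy shared across the toolkit."""


class DiscretusError(Exception):
    """Base class for all errors raised by discretus."""


class EmptyInputError(DiscretusError):
    """An input file or collection held no records."""


class AlignmentError(DiscretusError):
    """Sequences used as an alignment violate alignment invariants."""


class TreeError(DiscretusError):
    """A tree violates structural requirements."""


class NonBinaryTreeError(TreeError):
    """Tree contains a polytomy (or an unresolved internal node)."""


class NonUltrametricError(TreeError):
    """Root-to-tip path lengths differ by more than the tolerance."""


class UnknownTipError(TreeError, KeyError):
    """A requested tip label is not present in the tree."""


class InsufficientDataError(DiscretusError):
    """Not enough tips/sequences for the requested model or statistic."""


class MetadataError(DiscretusError):
    """Metadata is missing, inconsistent, or fails to join."""


class DomainError(DiscretusError, ValueError):
    """A parameter lies outside its mathematical domain."""


class FitError(DiscretusError):
    """An optimizer failed to converge or returned an invalid optimum."""
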