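"""Exception hierarchy shared across the package.

Every error a caller may want to branch on derives from
:class:`NeedleplotError`; transport problems are kept distinct from
"the service answered but had nothing" so pipelines can retry the
former and report the latter.
"""


class NeedleplotError(Exception):
    """Base class for all errors raised by this package."""


class TransportError(NeedleplotError):
    """The network layer failed (DNS, refused connection, timeout, 5xx)."""


class ResolutionError(NeedleplotError):
    """A gene symbol could not be resolved to a reviewed accession."""


class NotFoundError(NeedleplotError):
    """The service answered but knows no record for the identifier."""


class ArchitectureParseError(NeedleplotError):
    """A domain-architecture document is malformed; the message names the offending path."""


class VariantSpecError(NeedleplotError):
    """A variant spec string does not match the grammar."""


class LayoutError(NeedleplotError):
    """Geometry cannot accommodate the data (position out of range, too many stagger slots)."""


class GenerationError(NeedleplotError):
    """A synthetic fixture request is infeasible (e.g. domains cannot be packed)."""
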