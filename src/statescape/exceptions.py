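"""Exception hierarchy shared across the package."""


class StatescapeError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(StatescapeError, ValueError):
    """A parameter value violates its contract."""


class ValidationError(StatescapeError, ValueError):
    """Input data violate a structural precondition."""


class DimensionError(ValidationError):
    """Input has the wrong dimensionality for the requested operation."""


class EmptyLabelError(StatescapeError, KeyError):
    """A state label does not occur anywhere in the graph."""


class DisconnectedSupportError(StatescapeError, RuntimeError):
    """Distribution supports (or label nodes) span multiple graph components."""


# Optimal transport between supports in different components is infeasible;
# same failure mode, explicit alias for call sites that read better with it.
InfeasibleTransportError = DisconnectedSupportError


class DegenerateDataError(StatescapeError, ValueError):
    """Zero-variance data make the requested statistic undefined."""


class DesignError(StatescapeError, ValueError):
    """The statistical design is incomplete (e.g. a missing cell)."""
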