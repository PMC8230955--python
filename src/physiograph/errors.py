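"""Exception hierarchy shared across the package."""


class GraphError(Exception):
    """Base class for all graph-layer failures."""


class UnknownLabelError(GraphError):
    """A node or edge label that is not in the registered vocabulary."""


class MissingEndpointError(GraphError):
    """Edge creation referenced a node id that is not in the graph."""


class ConstraintViolationError(GraphError):
    """An integrity constraint rejected a mutation; the mutation was rolled back."""


class RetroactiveViolationError(GraphError):
    """Registering a constraint that existing graph contents already break."""


class TimelineError(GraphError):
    """Timeline-layer precondition failure (ordering, negativity, overlap)."""


class KindMismatchError(GraphError):
    """A signal series was bound to a measure of the wrong kind."""


class EpochGridMismatchError(GraphError):
    """Electrode measures of one channel do not share identical epoch boundaries."""


class UnknownSignalError(GraphError):
    """No measure with the requested signal_id exists."""


class ValidationError(Exception):
    """Bad user-supplied specification or configuration."""
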