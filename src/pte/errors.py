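"""Exception hierarchy for the PTE toolkit."""


class PTEError(Exception):
    """Base class for all toolkit errors."""


class FormatError(PTEError):
    """A delimited input file does not expose the required columns."""


class IntegrityError(PTEError):
    """A sorter assigned the same excerpt to more than one pile."""


class IncompleteSortError(PTEError):
    """A sorter did not assign every excerpt (and incompleteness was not allowed)."""


class CatalogMismatchError(PTEError):
    """Excerpt ids in the dataset are missing from the supplied catalogue, or vice versa."""


class UndefinedDistanceError(PTEError):
    """Conceptual distance 1/score requested for a similarity score of zero."""


class DisconnectedGroupError(PTEError):
    """A hand-supplied group induces a disconnected subgraph; within-group
    closeness is undefined."""


class DesignError(PTEError):
    """A planted-partition simulation design is infeasible or inconsistent."""


class SelectionError(PTEError):
    """No dendrogram level satisfies the requested partition constraint."""


class ConsistencyError(PTEError):
    """Two artefacts that must cover the same excerpt set do not."""
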