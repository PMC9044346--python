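"""Exception hierarchy for provlink.

Every error raised by the library derives from :class:`ProvlinkError` so
callers (and the CLI) can catch one base class.
"""


class ProvlinkError(Exception):
    """Base class for all provlink errors."""


class SchemaError(ProvlinkError):
    """A notebook document is missing required structure ("cells"/"metadata")."""


class ProvenanceSchemaError(SchemaError):
    """A stored provenance record violates the execution-record invariants."""


class NotACodeCell(ProvlinkError):
    """Provenance was requested on a markdown or raw cell."""


class NegativeDuration(ProvlinkError):
    """An execution's end time precedes its start time."""


class ExecutorFailure(ProvlinkError):
    """A cell's source could not be executed by the executor."""


class UnknownCell(ProvlinkError):
    """A cell selector did not resolve to any cell in the notebook."""


class NoSuchExecution(ProvlinkError):
    """No stored execution record matches the requested start time."""


class AmbiguousExecution(ProvlinkError):
    """Several records share the requested start time and no index was given."""


class NotAProvlinkGraph(ProvlinkError):
    """An RDF graph does not contain exactly one repr:Notebook node."""


class BrokenChain(ProvlinkError):
    """The isPrecededBy relation in a graph is not a total order over steps."""


class TurtleSyntaxError(ProvlinkError):
    """A turtle document could not be parsed."""


class QuerySyntaxError(ProvlinkError):
    """A SPARQL query could not be parsed."""


class UnsupportedFeature(ProvlinkError):
    """A SPARQL query uses features outside the supported floor."""


class UnknownReference(ProvlinkError):
    """An operation referenced an id that does not exist in the store."""


class CycleDetected(ProvlinkError):
    """A step predecessor chain would form a cycle."""


class UnknownVersion(ProvlinkError):
    """A version number does not exist for the entity."""


class UnknownExperiment(ProvlinkError):
    """An experiment id does not exist in the store."""


class UnknownNotebook(ProvlinkError):
    """A notebook id does not exist in the store."""


class UnknownNode(ProvlinkError):
    """A node id does not exist in a provenance view."""
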