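"""The closed RDF vocabulary used by provlink (version 1).

The toolkit describes experiments and notebook executions with a pinned
subset of three provenance vocabularies: W3C PROV-O (entities, agents,
activities), P-Plan (plans, steps, variables and their wiring), and the
REPRODUCE-ME extension that adds experiment-specific terms (datasets,
instruments, settings, roles, execution time).  Every class and property the
mappings emit appears in :data:`TERM_TABLE`; emitting anything else is a
programming error, which keeps the graphs queryable by the competency
queries and lets tests scan for vocabulary drift.

The ``repr:`` namespace IRI is pinned here in one place so the whole term
set can be re-aligned to a published ontology revision without touching the
mapping code.
"""

from rdflib import Namespace
from rdflib.namespace import RDF, XSD

VOCAB_VERSION = 1

REPR = Namespace("https://w3id.org/reproduceme#")
PPLAN = Namespace("http://purl.org/net/p-plan#")
PROV = Namespace("http://www.w3.org/ns/prov#")

#: Prefixes declared in every turtle document.
PREFIXES = {
    "repr": REPR,
    "p-plan": PPLAN,
    "prov": PROV,
    "rdf": Namespace(str(RDF)),
    "xsd": Namespace(str(XSD)),
}

CLASSES = frozenset(
    {
        REPR.Experiment,
        REPR.Notebook,
        PPLAN.Plan,
        PPLAN.Step,
        PPLAN.Variable,
        PROV.Entity,
        PROV.Agent,
        PROV.Activity,
    }
)

PROPERTIES = frozenset(
    {
        PPLAN.isStepOfPlan,
        PPLAN.isSubPlanOfPlan,
        PPLAN.isVariableOfPlan,
        PPLAN.isPrecededBy,
        PPLAN.hasInputVar,
        PPLAN.hasOutputVar,
        PPLAN.isInputVarOf,
        PPLAN.isOutputVarOf,
        PPLAN.correspondsToStep,
        PPLAN.correspondsToVariable,
        PROV.wasAttributedTo,
        PROV.generatedAtTime,
        PROV.startedAtTime,
        PROV.endedAtTime,
        PROV.hadMember,
        REPR.executionTime,
        REPR.hasDataset,
        REPR.hasRole,
        REPR.hasPart,
        REPR.hasSetting,
        REPR.name,
        REPR.isAvailableAt,
        REPR.reference,
        RDF.value,
        RDF.type,
    }
)

TERM_TABLE = CLASSES | PROPERTIES
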