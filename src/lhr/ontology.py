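"""Construction of the Linked Health Resource (LHR) integration ontology.

The LHR ontology models a person, their services, and every piece of health
or home-environment data those services expose, uniformly as *resources*:
anything identified by an HTTP URI is a resource, a service is the resource
at the root path of its URI, and a person is a resource owning all the
others.  Class and property axioms are deliberately restricted to RDFS plus
owl:TransitiveProperty / owl:inverseOf / owl:equivalentClass /
owl:equivalentProperty, so that the whole model closes under a handful of
cheap forward-chaining rules.

External vocabularies (FHIR RDF, SSN/SOSA, SemREST annotations, WoT Thing
Description) are bound to LHR terms by small *mapping extensions* — RDF
micro-documents whose axioms are restricted to subclass / subproperty /
equivalence statements with one side in the LHR namespace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdflib import Graph, Literal, Namespace, URIRef
from rdflib.namespace import OWL, RDF, RDFS
from rdflib.util import guess_format

from .errors import InvalidExtensionError, MalformedDocumentError
from .namespaces import FHIR, LHR, SEMREST, SOSA, SSN, TD, bind_namespaces

#: RDF serialization formats accepted and emitted throughout the package.
SUPPORTED_FORMATS = {"turtle", "ttl", "nt", "ntriples", "nt11", "xml", "json-ld"}

#: Predicates a mapping extension may use.
PERMITTED_MAPPING_PREDICATES = frozenset(
    {RDFS.subClassOf, RDFS.subPropertyOf, OWL.equivalentClass, OWL.equivalentProperty}
)

#: LHR classes, in declaration order.
LHR_CLASSES = (
    "Resource",
    "Service",
    "Person",
    "HealthResource",
    "EnvResource",
    "LDResource",
    "FHIRObservation",
    "HealthSSNResource",
    "EnvSSNResource",
    "DataItem",
    "ObservationData",
)

#: Direct subclass edges (child, parent) among LHR classes.
LHR_SUBCLASS_EDGES = (
    ("Service", "Resource"),
    ("Person", "Resource"),
    ("HealthResource", "Resource"),
    ("EnvResource", "Resource"),
    ("LDResource", "Resource"),
    ("FHIRObservation", "HealthResource"),
    ("HealthSSNResource", "HealthResource"),
    ("EnvSSNResource", "EnvResource"),
    ("ObservationData", "DataItem"),
)


def build_lhr_ontology(namespace: str | Namespace = LHR) -> Graph:
    """Build the LHR ontology as an :class:`rdflib.Graph`.

    Parameters
    ----------
    namespace:
        Namespace URI under which the LHR terms are minted.  The default is
        the package-wide :data:`~lhr.namespaces.LHR` constant.

    The output is deterministic: the same namespace always yields the same
    triple set (see :func:`canonical_nt` for a byte-stable serialization).
    """
    ns = Namespace(str(namespace))
    g = bind_namespaces(Graph(), lhr=ns)

    for name in LHR_CLASSES:
        g.add((ns[name], RDF.type, OWL.Class))
    for child, parent in LHR_SUBCLASS_EDGES:
        g.add((ns[child], RDFS.subClassOf, ns[parent]))

    # The resource-linking object-property hierarchy.  lhr:hasResource is
    # transitive so that a person reaches every resource of every service.
    g.add((ns.hasResource, RDF.type, OWL.ObjectProperty))
    g.add((ns.hasResource, RDF.type, OWL.TransitiveProperty))
    g.add((ns.hasResource, RDFS.domain, ns.Resource))
    g.add((ns.hasResource, RDFS.range, ns.Resource))
    g.add((ns.isResourceOf, RDF.type, OWL.ObjectProperty))
    g.add((ns.isResourceOf, OWL.inverseOf, ns.hasResource))
    for sub in ("hasHealthResource", "hasLDResource", "hasInterLinkedResource"):
        g.add((ns[sub], RDF.type, OWL.ObjectProperty))
        g.add((ns[sub], RDFS.subPropertyOf, ns.hasResource))
    g.add((ns.hasHealthResource, RDFS.domain, ns.Resource))
    g.add((ns.hasHealthResource, RDFS.range, ns.HealthResource))
    g.add((ns.hasLDResource, RDFS.domain, ns.Resource))
    g.add((ns.hasLDResource, RDFS.range, ns.LDResource))

    # The data-item property hierarchy: every source idiom for attaching an
    # observation value funnels into lhr:hasObservationData ⊑ lhr:hasDataItem.
    g.add((ns.hasDataItem, RDF.type, OWL.ObjectProperty))
    g.add((ns.hasDataItem, RDFS.range, ns.DataItem))
    g.add((ns.hasObservationData, RDF.type, OWL.ObjectProperty))
    g.add((ns.hasObservationData, RDFS.subPropertyOf, ns.hasDataItem))
    g.add((ns.hasObservationData, RDFS.range, ns.ObservationData))
    g.add((ns.hasSOSAObservationResult, RDF.type, OWL.ObjectProperty))
    g.add((ns.hasSOSAObservationResult, RDFS.subPropertyOf, ns.hasObservationData))
    g.add((ns["hasFHIRObservation.valueQuantity"], RDF.type, OWL.ObjectProperty))
    g.add((ns["hasFHIRObservation.valueQuantity"], RDFS.subPropertyOf, ns.hasObservationData))

    # Data-item payload properties: value, timestamp and the dereferenceable
    # value-type URI indicating the semantic meaning of the value.
    g.add((ns.hasDataValue, RDF.type, OWL.DatatypeProperty))
    g.add((ns.hasObservationDateTime, RDF.type, OWL.DatatypeProperty))
    g.add((ns.hasValueType, RDF.type, OWL.ObjectProperty))
    return g


def canonical_nt(graph: Graph) -> str:
    """Canonical serialization: sorted N-Triples, byte-identical across runs."""
    nt = graph.serialize(format="nt")
    return "\n".join(sorted(line for line in nt.splitlines() if line.strip())) + "\n"


@dataclass
class MappingExtension:
    """An RDF micro-document of axioms binding an external vocabulary to LHR.

    Axioms are restricted to ``rdfs:subClassOf``, ``rdfs:subPropertyOf``,
    ``owl:equivalentClass`` and ``owl:equivalentProperty``, each with one
    side in the LHR namespace (or a term previously mapped into it).
    """

    graph: Graph
    source_vocabulary: str
    label: str = ""

    @property
    def triples(self) -> set[tuple]:
        return set(self.graph)

    def __len__(self) -> int:
        return len(self.graph)

    def serialize(self, format: str = "turtle") -> str:
        return self.graph.serialize(format=_normalize_format(format))


@dataclass
class ValidationReport:
    """Outcome of checking a mapping extension against an ontology."""

    findings: list[str] = field(default_factory=list)
    offending_triples: list[tuple] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.findings


def _normalize_format(fmt: str) -> str:
    fmt = {"ttl": "turtle", "ntriples": "nt", "jsonld": "json-ld"}.get(fmt, fmt)
    if fmt not in SUPPORTED_FORMATS:
        from .errors import UnsupportedFormatError

        raise UnsupportedFormatError(f"unsupported RDF format: {fmt!r}")
    return fmt


def _extension_from_graph(g: Graph, source_vocabulary: str, label: str) -> MappingExtension:
    bind_namespaces(g)
    offending = [t for t in g if t[1] not in PERMITTED_MAPPING_PREDICATES]
    if offending:
        raise InvalidExtensionError(
            "mapping extension uses predicates outside the permitted set "
            "{rdfs:subClassOf, rdfs:subPropertyOf, owl:equivalentClass, "
            f"owl:equivalentProperty}}: {offending}",
            offending=offending,
        )
    return MappingExtension(graph=g, source_vocabulary=source_vocabulary, label=label)


def load_mapping_extension(
    document: str, format: str = "turtle", label: str = ""
) -> MappingExtension:
    """Parse an RDF document into a :class:`MappingExtension`.

    Raises
    ------
    MalformedDocumentError
        if the document does not parse in the named format.
    InvalidExtensionError
        if any triple uses a predicate outside the permitted axiom set.
    """
    fmt = _normalize_format(guess_format(format) or format)
    g = Graph()
    try:
        g.parse(data=document, format=fmt)
    except Exception as exc:  # rdflib raises format-specific parser errors
        raise MalformedDocumentError(str(exc), source=label or None) from exc
    lhr_ns = str(LHR)
    external = {
        str(term).rsplit("#", 1)[0] + "#" if "#" in str(term) else str(term).rsplit("/", 1)[0] + "/"
        for t in g
        for term in (t[0], t[2])
        if isinstance(term, URIRef) and not str(term).startswith(lhr_ns)
    }
    source_vocab = sorted(external)[0] if external else lhr_ns
    return _extension_from_graph(g, source_vocab, label)


def validate_mapping_extension(ext: MappingExtension, onto: Graph) -> ValidationReport:
    """Check that every LHR-side term of *ext* exists in the ontology graph.

    A term "exists" if it occurs anywhere in *onto* (as subject or object).
    The report lists one finding per axiom whose LHR-side term is unknown;
    the extension is valid iff the list is empty.
    """
    known = {t for triple in onto for t in (triple[0], triple[2]) if isinstance(t, URIRef)}
    lhr_ns = str(LHR)
    report = ValidationReport()
    for s, p, o in ext.graph:
        for term in (s, o):
            if isinstance(term, URIRef) and str(term).startswith(lhr_ns) and term not in known:
                report.findings.append(
                    f"axiom ({s.n3()} {p.n3()} {o.n3()}) references unknown LHR term {term.n3()}"
                )
                report.offending_triples.append((s, p, o))
    return report


def fhir_mapping_extension() -> MappingExtension:
    """FHIR RDF → LHR: observations and their value/datetime paths."""
    g = Graph()
    g.add((FHIR.Observation, OWL.equivalentClass, LHR.FHIRObservation))
    g.add(
        (
            FHIR["Observation.valueQuantity"],
            OWL.equivalentProperty,
            LHR["hasFHIRObservation.valueQuantity"],
        )
    )
    g.add((FHIR["Observation.effectiveDateTime"], RDFS.subPropertyOf, LHR.hasObservationDateTime))
    return _extension_from_graph(g, str(FHIR), "fhir")


def sosa_mapping_extension(polarity: str = "env") -> MappingExtension:
    """SSN/SOSA → LHR.

    A SOSA observation from a WoT device can carry either health data or
    home-environment data; *polarity* selects which LHR branch
    ``sosa:Observation`` is made equivalent to (``"env"`` →
    lhr:EnvSSNResource, ``"health"`` → lhr:HealthSSNResource).
    """
    if polarity not in ("env", "health"):
        raise ValueError(f"polarity must be 'env' or 'health', got {polarity!r}")
    target = LHR.EnvSSNResource if polarity == "env" else LHR.HealthSSNResource
    g = Graph()
    g.add((SSN.System, RDFS.subClassOf, LHR.Service))
    g.add((SOSA.Sensor, RDFS.subClassOf, LHR.Resource))
    g.add((SOSA.Observation, OWL.equivalentClass, target))
    g.add((SOSA.hasResult, OWL.equivalentProperty, LHR.hasSOSAObservationResult))
    g.add((SOSA.resultTime, RDFS.subPropertyOf, LHR.hasObservationDateTime))
    g.add((SOSA.madeObservation, RDFS.subPropertyOf, LHR.hasResource))
    return _extension_from_graph(g, str(SOSA), f"sosa-{polarity}")


def semrest_mapping_extension(polarity: str = "health") -> MappingExtension:
    """SemREST annotation vocabulary → LHR (representation units, data items)."""
    if polarity not in ("env", "health"):
        raise ValueError(f"polarity must be 'env' or 'health', got {polarity!r}")
    target = LHR.HealthResource if polarity == "health" else LHR.EnvResource
    g = Graph()
    g.add((SEMREST.Representation, RDFS.subClassOf, target))
    g.add((SEMREST.dataItem, RDFS.subPropertyOf, LHR.hasDataItem))
    g.add((SEMREST.hasValue, RDFS.subPropertyOf, LHR.hasDataValue))
    return _extension_from_graph(g, str(SEMREST), f"semrest-{polarity}")


def td_mapping_extension(polarity: str = "env") -> MappingExtension:
    """WoT Thing Description → LHR (things as health or environment resources)."""
    if polarity not in ("env", "health"):
        raise ValueError(f"polarity must be 'env' or 'health', got {polarity!r}")
    target = LHR.EnvResource if polarity == "env" else LHR.HealthResource
    g = Graph()
    g.add((TD.Thing, RDFS.subClassOf, target))
    return _extension_from_graph(g, str(TD), f"td-{polarity}")


def builtin_mapping_extensions(
    sosa_polarity: str = "env",
    semrest_polarity: str = "health",
    td_polarity: str = "env",
) -> list[MappingExtension]:
    """The four built-in vocabulary mappings: FHIR, SSN/SOSA, SemREST, WoT TD."""
    return [
        fhir_mapping_extension(),
        sosa_mapping_extension(sosa_polarity),
        semrest_mapping_extension(semrest_polarity),
        td_mapping_extension(td_polarity),
    ]
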