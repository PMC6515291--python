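"""Source adapters: the data-API and aggregation layers of the pipeline.

Each adapter turns one service's representation — FHIR/RDF observations,
SSN/SOSA sensor observations, a SemREST-annotated JSON body with its JSON-LD
context, or plain Linked Data — into a :class:`ResourceGraph`: the parsed
triples, skolemized blank nodes, the service root URI, and the candidate
representation units (the nodes that carry integrable content, as opposed to
request/response scaffolding).

Adapters never rewrite source data; normalization into the LHR data-item
model happens downstream in the integrator.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

from rdflib import BNode, Graph, URIRef
from rdflib.compare import to_canonical_graph
from rdflib.namespace import RDF
from rdflib.util import guess_format

from .errors import MalformedDocumentError
from .namespaces import FHIR, LHR, SEMREST, SOSA, bind_namespaces
from .reasoner import AxiomSet, forward_chain

SOURCE_KINDS = ("fhir-rdf", "sosa-rdf", "semrest-json", "linked-data")

#: Classes a representation unit must reach through subclass closure.
UNIT_TARGET_CLASSES = (LHR.HealthResource, LHR.EnvResource, LHR.LDResource)


@dataclass
class ResourceGraph:
    """One service's aggregated semantic resource graph."""

    graph: Graph
    service_root: URIRef
    source_label: str = ""
    format_origin: str = "linked-data"
    polarity: str | None = None
    candidate_units: list[URIRef] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.graph)


@dataclass(frozen=True)
class RepresentationUnit:
    """A node carrying integrable health/environment content.

    ``target_class`` is the most specific LHR class the node's (possibly
    inferred) types reach; ``tags`` are its semantic annotations; ``linked``
    the resources it links onward to.
    """

    node: URIRef
    target_class: URIRef
    tags: frozenset = frozenset()
    linked: frozenset = frozenset()


def skolemize(graph: Graph, service_root: str | URIRef) -> Graph:
    """Replace blank nodes with deterministic service-scoped URIs.

    The graph is first canonicalized (RGDA1 labels), so the skolem URI of a
    blank node depends only on the graph's structure, never on parse order:
    parsing the same document twice yields identical graphs, and graphs from
    different services can never collide.
    """
    root = str(service_root).rstrip("/")
    canonical = to_canonical_graph(graph)

    def skolem(node):
        if isinstance(node, BNode):
            digest = hashlib.sha1(str(node).encode()).hexdigest()
            return URIRef(f"{root}/.well-known/genid/{digest}")
        return node

    out = bind_namespaces(Graph())
    for prefix, ns in graph.namespaces():
        out.bind(prefix, ns)
    for s, p, o in canonical:
        out.add((skolem(s), p, skolem(o)))
    return out


def _parse_rdf(text: str, format: str, label: str) -> Graph:
    fmt = guess_format(format) or format
    g = Graph()
    try:
        g.parse(data=text, format=fmt)
    except Exception as exc:
        raise MalformedDocumentError(str(exc), source=label or None) from exc
    return g


def parse_fhir_rdf(text: str, format: str = "turtle", service_root: str = "") -> ResourceGraph:
    """Parse a FHIR/RDF document; every ``fhir:Observation`` node is a
    candidate representation unit."""
    g = skolemize(_parse_rdf(text, format, "fhir-rdf"), service_root)
    units = sorted(set(g.subjects(RDF.type, FHIR.Observation)))
    warnings = [] if units or len(g) == 0 else ["empty-unit: no fhir:Observation node found"]
    return ResourceGraph(
        graph=g,
        service_root=URIRef(str(service_root)),
        source_label="fhir-rdf",
        format_origin="fhir-rdf",
        candidate_units=units,
        warnings=warnings,
    )


def parse_sosa_rdf(
    text: str, format: str = "turtle", service_root: str = "", polarity: str = "env"
) -> ResourceGraph:
    """Parse an SSN/SOSA document; every ``sosa:Observation`` is a candidate
    unit, classified as environment or health data per *polarity*."""
    if polarity not in ("env", "health"):
        raise ValueError(f"polarity must be 'env' or 'health', got {polarity!r}")
    g = skolemize(_parse_rdf(text, format, "sosa-rdf"), service_root)
    units = sorted(set(g.subjects(RDF.type, SOSA.Observation)))
    warnings = [
        f"missing-result: {obs}" for obs in units if (obs, SOSA.hasResult, None) not in g
    ]
    return ResourceGraph(
        graph=g,
        service_root=URIRef(str(service_root)),
        source_label="sosa-rdf",
        format_origin="sosa-rdf",
        polarity=polarity,
        candidate_units=units,
        warnings=warnings,
    )


def _json_keys(obj) -> set[str]:
    keys: set[str] = set()
    if isinstance(obj, dict):
        for k, v in obj.items():
            if not k.startswith("@"):
                keys.add(k)
            keys |= _json_keys(v)
    elif isinstance(obj, list):
        for v in obj:
            keys |= _json_keys(v)
    return keys


def parse_semrest(body: str, context: str, service_root: str = "") -> ResourceGraph:
    """Expand an annotated JSON body under its JSON-LD context.

    The body is an ordinary Web-API response; the context maps its keys to
    vocabulary terms (SemREST annotation).  Keys the context does not map
    are dropped by expansion and reported as ``unmapped-key`` warnings.
    """
    try:
        body_obj = json.loads(body)
    except json.JSONDecodeError as exc:
        raise MalformedDocumentError(f"invalid JSON body: {exc}", source="semrest-json") from exc
    try:
        ctx_obj = json.loads(context)
    except json.JSONDecodeError as exc:
        raise MalformedDocumentError(
            f"invalid JSON-LD context: {exc}", source="semrest-json"
        ) from exc
    ctx = ctx_obj.get("@context", ctx_obj)
    if not isinstance(body_obj, dict):
        raise MalformedDocumentError("JSON body must be an object", source="semrest-json")

    doc = dict(body_obj)
    doc["@context"] = ctx
    g = Graph()
    try:
        g.parse(data=json.dumps(doc), format="json-ld")
    except Exception as exc:
        raise MalformedDocumentError(str(exc), source="semrest-json") from exc
    g = skolemize(g, service_root)

    mapped = {k for k in ctx if not k.startswith("@")} if isinstance(ctx, dict) else set()
    has_vocab = isinstance(ctx, dict) and "@vocab" in ctx
    unmapped = sorted(_json_keys(body_obj) - mapped) if not has_vocab else []
    warnings = [f"unmapped-key: {k}" for k in unmapped]

    units = sorted(set(g.subjects(RDF.type, SEMREST.Representation)))
    return ResourceGraph(
        graph=g,
        service_root=URIRef(str(service_root)),
        source_label="semrest-json",
        format_origin="semrest-json",
        polarity="health",
        candidate_units=units,
        warnings=warnings,
    )


def parse_linked_data(text: str, format: str = "turtle", service_root: str = "") -> ResourceGraph:
    """Parse a Linked Data document.

    Every URI subject under the service root becomes a candidate unit and is
    classified as the generic ``lhr:LDResource`` (Linked Data is usually not
    about a single person, so no finer health/env class applies); external
    subjects' triples are retained but yield no units.
    """
    g = skolemize(_parse_rdf(text, format, "linked-data"), service_root)
    root = str(service_root)
    units = sorted(
        {
            s
            for s in g.subjects(unique=True)
            if isinstance(s, URIRef) and str(s).startswith(root) and "/.well-known/genid/" not in str(s)
        }
    )
    for u in units:
        g.add((u, RDF.type, LHR.LDResource))
    return ResourceGraph(
        graph=g,
        service_root=URIRef(root),
        source_label="linked-data",
        format_origin="linked-data",
        candidate_units=units,
        warnings=[],
    )


def identify_representation_units(
    source: ResourceGraph, axioms: AxiomSet
) -> list[RepresentationUnit]:
    """Select the representation units of a source graph.

    A node is a unit iff its (possibly inferred) type reaches
    ``lhr:HealthResource``, ``lhr:EnvResource`` or ``lhr:LDResource``
    through subclass closure under *axioms* (ontology plus the applicable
    mapping extensions).  Request/response scaffolding whose types never
    reach those classes is excluded.  Results are sorted by node URI.
    """
    closed = forward_chain(source.graph, axioms)
    targets = set(UNIT_TARGET_CLASSES)
    types_of: dict[URIRef, set] = {}
    for s, p, o in closed.triples:
        if p == RDF.type and isinstance(s, URIRef) and isinstance(o, URIRef):
            types_of.setdefault(s, set()).add(o)

    sup_c = axioms.superclasses
    units: list[RepresentationUnit] = []
    for node in sorted(types_of):
        reaching = {
            c
            for c in types_of[node]
            if str(c).startswith(str(LHR)) and (sup_c.get(c, {c}) & targets or c in targets)
        }
        if not reaching:
            continue
        # most specific: the class subsumed by the most others in the set
        target = max(reaching, key=lambda c: (len(sup_c.get(c, {c}) & reaching), str(c)))
        tags = frozenset(
            t
            for item in closed.triples
            if item[1] == LHR.hasDataItem and item[0] == node
            for t in _item_tags(closed.triples, item[2])
        )
        linked = frozenset(
            o
            for s, p, o in closed.triples
            if s == node and p == LHR.hasResource and isinstance(o, URIRef) and o != node
        )
        units.append(RepresentationUnit(node=node, target_class=target, tags=tags, linked=linked))
    return units


def _item_tags(triples, item):
    return {o for s, p, o in triples if s == item and p == SEMREST.hasTag and isinstance(o, URIRef)}
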