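"""Information-resource integration layer.

Merges per-service resource graphs under the LHR ontology into one
person-rooted, inference-closed graph:

* the person is typed ``lhr:Person`` and linked to every service with the
  transitive ``lhr:hasResource``;
* each service is typed ``lhr:Service`` and linked to its representation
  units, so transitivity alone makes every unit reachable from the person;
* each source idiom for carrying an observation value (FHIR value-quantity
  nodes, SOSA results, SemREST data items) is normalized into canonical
  ``lhr:DataItem`` triples — value, ISO-8601 date-time, and a value-type URI
  naming the semantic meaning of the value (a terminology code, an observed
  property, or a semantic tag);
* the union is materialized to its forward-chaining fixpoint.

Units of measure are deliberately not normalized into data items; the
source triples are preserved in the graph for lookup.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF, RDFS, XSD

from .adapters import RepresentationUnit, ResourceGraph, identify_representation_units
from .namespaces import FHIR, LHR, LHR_NS, SEMREST, SOSA, bind_namespaces
from .ontology import (
    MappingExtension,
    _normalize_format,
    build_lhr_ontology,
    builtin_mapping_extensions,
    validate_mapping_extension,
)
from .errors import InvalidExtensionError
from .reasoner import ClosedGraph, entails, extract_axioms, forward_chain


@dataclass(frozen=True)
class PersonRef:
    """The person owning the integrated resources."""

    uri: URIRef
    name: str | None = None

    @staticmethod
    def mint(name: str, base: str | None = None) -> "PersonRef":
        base = (base or LHR_NS.rstrip("#/")) + "/person/"
        slug = re.sub(r"[^a-z0-9]+", "-", name.lower()).strip("-") or "anonymous"
        return PersonRef(uri=URIRef(base + slug), name=name)


@dataclass
class DataItem:
    """A normalized observation record extracted from the integrated graph."""

    subject: URIRef  # the owning representation unit
    node: URIRef  # the data-item node itself
    value: object  # python value of the literal, or None
    datetime: str | None  # ISO-8601 timestamp/date, or None
    value_type: URIRef | None
    source_service: URIRef | None = None


@dataclass
class IntegratedGraph:
    """The merged, inference-closed, person-rooted resource graph."""

    closed: ClosedGraph
    person: PersonRef
    services: list[URIRef] = field(default_factory=list)
    units: list[RepresentationUnit] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def graph(self) -> Graph:
        return self.closed.to_graph()

    def entails(self, triple) -> bool:
        return entails(self.closed, triple)


def _fuse_datetime(date: str | None, time: str | None, warnings: list[str], node) -> str | None:
    if date is None:
        return None
    if time is None:
        warnings.append(f"assumed-midnight: {node}")
        time = "00:00:00"
    return f"{date}T{time}"


def _normalize_source(source: ResourceGraph, warnings: list[str]) -> set[tuple]:
    """Materialize canonical lhr:DataItem triples for one source's idiom."""
    g = source.graph
    out: set[tuple] = set()

    if source.format_origin == "fhir-rdf":
        for obs in g.subjects(RDF.type, FHIR.Observation):
            dt = g.value(obs, FHIR["Observation.effectiveDateTime"])
            code = g.value(obs, FHIR["Observation.code"])
            for vq in g.objects(obs, FHIR["Observation.valueQuantity"]):
                value = g.value(vq, FHIR["Quantity.value"])
                if value is not None:
                    out.add((vq, LHR.hasDataValue, value))
                else:
                    warnings.append(f"missing-value: {vq}")
                if dt is not None:
                    out.add((vq, LHR.hasObservationDateTime, _as_datetime(dt)))
                if isinstance(code, URIRef):
                    out.add((vq, LHR.hasValueType, code))

    elif source.format_origin == "sosa-rdf":
        for obs in g.subjects(RDF.type, SOSA.Observation):
            rt = g.value(obs, SOSA.resultTime)
            prop = g.value(obs, SOSA.observedProperty)
            for res in g.objects(obs, SOSA.hasResult):
                value = g.value(res, RDF.value)
                if value is not None:
                    out.add((res, LHR.hasDataValue, value))
                else:
                    warnings.append(f"missing-value: {res}")
                if rt is not None:
                    out.add((res, LHR.hasObservationDateTime, _as_datetime(rt)))
                if isinstance(prop, URIRef):
                    out.add((res, LHR.hasValueType, prop))

    elif source.format_origin == "semrest-json":
        for owner, item in g.subject_objects(SEMREST.dataItem):
            out.add((owner, LHR.hasObservationData, item))
            value = g.value(item, SEMREST.hasValue)
            if value is not None:
                out.add((item, LHR.hasDataValue, value))
            else:
                warnings.append(f"missing-value: {item}")
            date = g.value(item, SEMREST.hasDate)
            time = g.value(item, SEMREST.hasTime)
            fused = _fuse_datetime(
                str(date) if date is not None else None,
                str(time) if time is not None else None,
                warnings,
                item,
            )
            if fused is not None:
                out.add((item, LHR.hasObservationDateTime, Literal(fused, datatype=XSD.dateTime)))
            tag = g.value(item, SEMREST.hasTag)
            if isinstance(tag, URIRef):
                out.add((item, LHR.hasValueType, tag))
    return out


def _as_datetime(lit) -> Literal:
    if isinstance(lit, Literal) and lit.datatype in (XSD.dateTime, XSD.date):
        return lit
    return Literal(str(lit), datatype=XSD.dateTime)


def default_extensions(sources: list[ResourceGraph]) -> list[MappingExtension]:
    """Built-in extensions with SOSA/SemREST polarity taken from the sources.

    If sources mix both SOSA polarities, both equivalence variants are
    returned; dual typing is permitted (no disjointness axiom exists).
    """
    sosa_pols = {s.polarity or "env" for s in sources if s.format_origin == "sosa-rdf"}
    semrest_pols = {s.polarity or "health" for s in sources if s.format_origin == "semrest-json"}
    exts = builtin_mapping_extensions(
        sosa_polarity=next(iter(sosa_pols)) if len(sosa_pols) == 1 else "env",
        semrest_polarity=next(iter(semrest_pols)) if len(semrest_pols) == 1 else "health",
    )
    from .ontology import semrest_mapping_extension, sosa_mapping_extension

    if len(sosa_pols) > 1:
        exts.append(sosa_mapping_extension("health"))
    if len(semrest_pols) > 1:
        exts.append(semrest_mapping_extension("env"))
    return exts


def integrate(
    person: PersonRef,
    sources: list[ResourceGraph],
    extensions: list[MappingExtension] | None = None,
    onto: Graph | None = None,
) -> IntegratedGraph:
    """Merge per-service graphs into one closed, person-rooted graph."""
    onto = onto if onto is not None else build_lhr_ontology()
    extensions = extensions if extensions is not None else default_extensions(sources)

    warnings: list[str] = []
    for ext in extensions:
        report = validate_mapping_extension(ext, onto)
        if not report.valid:
            raise InvalidExtensionError(
                f"extension {ext.label or ext.source_vocabulary!r} references unknown LHR terms: "
                + "; ".join(report.findings),
                offending=report.offending_triples,
            )

    axioms = extract_axioms([onto, *extensions])

    asserted: set[tuple] = set(onto)
    for ext in extensions:
        asserted |= set(ext.graph)

    asserted.add((person.uri, RDF.type, LHR.Person))
    if person.name:
        asserted.add((person.uri, RDFS.label, Literal(person.name)))

    services: list[URIRef] = []
    units: list[RepresentationUnit] = []
    seen_units: dict[URIRef, URIRef] = {}
    for source in sources:
        warnings.extend(f"{source.source_label}: {w}" for w in source.warnings)
        if not _covered(source, extensions):
            warnings.append(
                f"no mapping extension covers source vocabulary of {source.source_label!r}"
            )
        root = source.service_root
        if root not in services:
            services.append(root)
        asserted |= set(source.graph)
        asserted.add((root, RDF.type, LHR.Service))
        asserted.add((person.uri, LHR.hasResource, root))
        # per-source polarity typing for SOSA observations (the adapter's
        # classification wins over whichever global variant is loaded)
        if source.format_origin == "sosa-rdf":
            cls = LHR.EnvSSNResource if (source.polarity or "env") == "env" else LHR.HealthSSNResource
            for u in source.candidate_units:
                asserted.add((u, RDF.type, cls))
        for unit in identify_representation_units(source, axioms):
            if unit.node in seen_units and seen_units[unit.node] != root:
                warnings.append(f"duplicate-unit: {unit.node} (multiple services)")
            seen_units.setdefault(unit.node, root)
            asserted.add((root, LHR.hasResource, unit.node))
            asserted.add((unit.node, LHR.isResourceOf, root))
            units.append(unit)
        asserted |= _normalize_source(source, warnings)

    closed = forward_chain(asserted, axioms)
    return IntegratedGraph(
        closed=closed, person=person, services=services, units=units, warnings=warnings
    )


def _covered(source: ResourceGraph, extensions: list[MappingExtension]) -> bool:
    needed = {
        "fhir-rdf": str(FHIR),
        "sosa-rdf": str(SOSA),
        "semrest-json": str(SEMREST),
    }.get(source.format_origin)
    return needed is None or any(ext.source_vocabulary == needed for ext in extensions)


def extract_data_items(graph: IntegratedGraph) -> tuple[list[DataItem], list[str]]:
    """One :class:`DataItem` per (unit, lhr:hasObservationData, node) pair.

    Subproperty closure has already run, so FHIR value-quantities, SOSA
    results and SemREST data items all appear.  Items are sorted by
    (subject, datetime); a node with no value literal yields an item with
    ``value=None`` plus a warning.
    """
    triples = graph.closed.triples
    service_of = {}
    for s, p, o in triples:
        if p == LHR.isResourceOf and o in set(graph.services):
            service_of[s] = o

    values: dict = {}
    datetimes: dict = {}
    vtypes: dict = {}
    for s, p, o in triples:
        if p == LHR.hasDataValue:
            values[s] = o
        elif p == LHR.hasObservationDateTime:
            datetimes[s] = o
        elif p == LHR.hasValueType:
            vtypes[s] = o

    items: list[DataItem] = []
    warnings: list[str] = []
    for s, p, o in triples:
        if p != LHR.hasObservationData:
            continue
        value = values.get(o)
        if value is None:
            warnings.append(f"missing-value: data node {o} has no lhr:hasDataValue")
        dt = datetimes.get(o)
        items.append(
            DataItem(
                subject=s,
                node=o,
                value=value.toPython() if value is not None else None,
                datetime=str(dt) if dt is not None else None,
                value_type=vtypes.get(o),
                source_service=service_of.get(s),
            )
        )
    items.sort(key=lambda it: (str(it.subject), it.datetime or "", str(it.node)))
    return items, warnings


def serialize(graph: IntegratedGraph, format: str = "turtle", asserted_only: bool = False) -> str:
    """Serialize the integrated graph; re-parsing (and re-closing, when
    ``asserted_only``) reproduces an isomorphic graph."""
    fmt = _normalize_format(format)
    g = graph.closed.to_graph(asserted_only=asserted_only)
    return g.serialize(format=fmt)
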