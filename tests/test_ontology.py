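"""The LHR vocabulary: class/property axioms, mapping extensions, validation."""

import pytest
from rdflib import Graph, URIRef
from rdflib.compare import isomorphic
from rdflib.namespace import OWL, RDF, RDFS

from lhr import (
    InvalidExtensionError,
    MalformedDocumentError,
    build_lhr_ontology,
    builtin_mapping_extensions,
    canonical_nt,
    extract_axioms,
    load_mapping_extension,
    validate_mapping_extension,
)
from lhr.namespaces import FHIR, LHR, SEMREST, SOSA, SSN, TD
from lhr.ontology import LHR_CLASSES, LHR_SUBCLASS_EDGES

# Every schema assertion the integration model relies on, checked one by one.
EXPECTED_DIRECT_TRIPLES = [
    (LHR.Service, RDFS.subClassOf, LHR.Resource),
    (LHR.Person, RDFS.subClassOf, LHR.Resource),
    (LHR.HealthResource, RDFS.subClassOf, LHR.Resource),
    (LHR.EnvResource, RDFS.subClassOf, LHR.Resource),
    (LHR.LDResource, RDFS.subClassOf, LHR.Resource),
    (LHR.FHIRObservation, RDFS.subClassOf, LHR.HealthResource),
    (LHR.HealthSSNResource, RDFS.subClassOf, LHR.HealthResource),
    (LHR.EnvSSNResource, RDFS.subClassOf, LHR.EnvResource),
    (LHR.hasResource, RDF.type, OWL.TransitiveProperty),
    (LHR.isResourceOf, OWL.inverseOf, LHR.hasResource),
    (LHR.hasHealthResource, RDFS.subPropertyOf, LHR.hasResource),
    (LHR.hasLDResource, RDFS.subPropertyOf, LHR.hasResource),
    (LHR.hasInterLinkedResource, RDFS.subPropertyOf, LHR.hasResource),
    (LHR.hasHealthResource, RDFS.domain, LHR.Resource),
    (LHR.hasHealthResource, RDFS.range, LHR.HealthResource),
    (LHR.hasLDResource, RDFS.domain, LHR.Resource),
    (LHR.hasLDResource, RDFS.range, LHR.LDResource),
    (LHR.hasObservationData, RDFS.subPropertyOf, LHR.hasDataItem),
    (LHR.hasSOSAObservationResult, RDFS.subPropertyOf, LHR.hasObservationData),
    (LHR["hasFHIRObservation.valueQuantity"], RDFS.subPropertyOf, LHR.hasObservationData),
]

EXPECTED_MAPPING_TRIPLES = [
    (FHIR.Observation, OWL.equivalentClass, LHR.FHIRObservation),
    (FHIR["Observation.valueQuantity"], OWL.equivalentProperty, LHR["hasFHIRObservation.valueQuantity"]),
    (FHIR["Observation.effectiveDateTime"], RDFS.subPropertyOf, LHR.hasObservationDateTime),
    (SSN.System, RDFS.subClassOf, LHR.Service),
    (SOSA.Sensor, RDFS.subClassOf, LHR.Resource),
    (SOSA.Observation, OWL.equivalentClass, LHR.EnvSSNResource),
    (SOSA.hasResult, OWL.equivalentProperty, LHR.hasSOSAObservationResult),
    (SOSA.resultTime, RDFS.subPropertyOf, LHR.hasObservationDateTime),
    (SOSA.madeObservation, RDFS.subPropertyOf, LHR.hasResource),
    (SEMREST.Representation, RDFS.subClassOf, LHR.HealthResource),
    (SEMREST.dataItem, RDFS.subPropertyOf, LHR.hasDataItem),
    (SEMREST.hasValue, RDFS.subPropertyOf, LHR.hasDataValue),
    (TD.Thing, RDFS.subClassOf, LHR.EnvResource),
]


def test_all_classes_declared(ontology):
    for name in LHR_CLASSES:
        assert (LHR[name], RDF.type, OWL.Class) in ontology


@pytest.mark.parametrize("triple", EXPECTED_DIRECT_TRIPLES, ids=lambda t: f"{t[0].rsplit('#')[-1]}-{t[2].rsplit('#')[-1]}")
def test_ontology_asserts_each_schema_triple(ontology, triple):
    assert triple in ontology


@pytest.mark.parametrize("triple", EXPECTED_MAPPING_TRIPLES, ids=lambda t: t[0].rsplit("/", 1)[-1])
def test_builtin_extensions_assert_each_mapping(extensions, triple):
    union = {t for ext in extensions for t in ext.graph}
    assert triple in union


def test_every_class_under_resource_via_closure(axioms):
    """All classes except the data-model classes sit under lhr:Resource."""
    for name in LHR_CLASSES:
        cls = LHR[name]
        under = LHR.Resource in axioms.superclasses.get(cls, set())
        assert under == (name not in ("DataItem", "ObservationData"))


def test_ontology_deterministic_canonical_serialization():
    assert canonical_nt(build_lhr_ontology()) == canonical_nt(build_lhr_ontology())


def test_ontology_round_trips_isomorphically(ontology):
    for fmt in ("turtle", "nt", "xml", "json-ld"):
        text = ontology.serialize(format=fmt)
        assert isomorphic(Graph().parse(data=text, format=fmt), ontology), fmt


def test_custom_namespace_is_honored():
    g = build_lhr_ontology("https://other.example.net/vocab#")
    assert (URIRef("https://other.example.net/vocab#Person"), RDF.type, OWL.Class) in g


def test_sosa_health_polarity_variant():
    from lhr.ontology import sosa_mapping_extension

    ext = sosa_mapping_extension("health")
    assert (SOSA.Observation, OWL.equivalentClass, LHR.HealthSSNResource) in ext.graph


def test_load_extension_roundtrip_and_sizes():
    ttl = (
        "@prefix semrest: <https://example.org/semrest#> .\n"
        "@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .\n"
        "@prefix lhr: <https://example.org/lhr#> .\n"
        "semrest:Representation rdfs:subClassOf lhr:HealthResource .\n"
    )
    ext = load_mapping_extension(ttl, "turtle")
    assert len(ext) == 1
    assert ext.source_vocabulary == str(SEMREST)
    assert len(load_mapping_extension("", "turtle")) == 0


def test_load_extension_rejects_forbidden_predicate():
    ttl = "<https://a.example/x> a <https://a.example/y> ."
    with pytest.raises(InvalidExtensionError) as exc:
        load_mapping_extension(ttl, "turtle")
    assert exc.value.offending


def test_load_extension_reports_parse_failure():
    with pytest.raises(MalformedDocumentError):
        load_mapping_extension("this is not turtle @@", "turtle")


def test_validate_flags_misspelled_lhr_term(ontology):
    ttl = (
        "@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .\n"
        "<https://a.example/T> rdfs:subClassOf <https://example.org/lhr#HealtResource> .\n"
    )
    report = validate_mapping_extension(load_mapping_extension(ttl), ontology)
    assert not report.valid
    assert len(report.findings) == 1


def test_validate_builtin_extensions_and_empty(ontology, extensions):
    for ext in extensions:
        assert validate_mapping_extension(ext, ontology).valid
    assert validate_mapping_extension(load_mapping_extension(""), ontology).valid


def test_no_subclass_cycles_beyond_equivalence(axioms):
    """Mapping extensions must not create subclass cycles except the mutual
    pairs that encode owl:equivalentClass."""
    import networkx as nx

    g = nx.DiGraph()
    for a, b in axioms.subclass_pairs:
        if a != b:
            g.add_edge(a, b)
    for comp in nx.strongly_connected_components(g):
        assert len(comp) <= 2, f"unexpected subclass cycle: {comp}"


def test_serialize_unknown_format_raises(extensions):
    from lhr import UnsupportedFormatError

    with pytest.raises(UnsupportedFormatError):
        extensions[0].serialize("trix-nope")
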