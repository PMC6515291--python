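"""Source adapters: parsing, skolemization, and representation-unit selection."""

import json

import pytest
from rdflib.compare import isomorphic
from rdflib.namespace import RDF

from lhr import (
    MalformedDocumentError,
    gen_fhir_observation,
    gen_fitbit_steps,
    gen_sosa_observations,
    identify_representation_units,
    parse_fhir_rdf,
    parse_linked_data,
    parse_semrest,
    parse_sosa_rdf,
)
from lhr.fixtures import FITBIT_ROOT, HEALTHCARE_ROOT, WOT_ROOT
from lhr.namespaces import LHR


def test_fhir_blood_glucose_yields_one_candidate_unit():
    rg = parse_fhir_rdf(gen_fhir_observation(), "turtle", HEALTHCARE_ROOT)
    assert len(rg.candidate_units) == 1
    assert str(rg.candidate_units[0]).endswith("/Observation/f001")
    assert not rg.warnings


def test_fhir_three_observations_three_units():
    docs = "\n".join(
        gen_fhir_observation(resource_id=f"f00{i}", value=5.0 + i) for i in range(1, 4)
    )
    rg = parse_fhir_rdf(docs, "turtle", HEALTHCARE_ROOT)
    assert len(rg.candidate_units) == 3


def test_fhir_empty_document_and_missing_observation_warning():
    empty = parse_fhir_rdf("", "turtle", HEALTHCARE_ROOT)
    assert len(empty) == 0 and not empty.candidate_units
    no_obs = parse_fhir_rdf(
        "<https://a.example/x> <https://a.example/p> <https://a.example/y> .",
        "turtle",
        "https://a.example",
    )
    assert not no_obs.candidate_units
    assert any(w.startswith("empty-unit") for w in no_obs.warnings)


def test_parse_failure_raises_malformed_document():
    with pytest.raises(MalformedDocumentError):
        parse_fhir_rdf("@@ not turtle", "turtle", HEALTHCARE_ROOT)
    with pytest.raises(MalformedDocumentError):
        parse_sosa_rdf("<<<", "turtle", WOT_ROOT)
    with pytest.raises(MalformedDocumentError):
        parse_linked_data("][", "turtle", "https://x.example")


def test_skolemization_is_deterministic():
    doc = gen_fhir_observation()
    g1 = parse_fhir_rdf(doc, "turtle", HEALTHCARE_ROOT).graph
    g2 = parse_fhir_rdf(doc, "turtle", HEALTHCARE_ROOT).graph
    assert set(g1) == set(g2)  # identical, not merely isomorphic
    assert all("/.well-known/genid/" in str(s) for s in g1.subjects() if "Observation" not in str(s))


def test_sosa_two_observations_env_polarity():
    rg = parse_sosa_rdf(gen_sosa_observations(), "turtle", WOT_ROOT, "env")
    assert len(rg.candidate_units) == 2
    assert rg.polarity == "env"
    assert not rg.warnings


def test_sosa_missing_result_flagged_but_retained():
    doc = (
        "@prefix sosa: <http://www.w3.org/ns/sosa/> .\n"
        "<https://w.example/obs/1> a sosa:Observation .\n"
    )
    rg = parse_sosa_rdf(doc, "turtle", "https://w.example", "health")
    assert len(rg.candidate_units) == 1
    assert any(w.startswith("missing-result") for w in rg.warnings)


def test_semrest_three_day_body(alice_bundle):
    body, context, _ = gen_fitbit_steps(n_days=3, seed=42)
    rg = parse_semrest(body, context, FITBIT_ROOT)
    assert len(rg.candidate_units) == 1
    assert str(rg.candidate_units[0]).endswith("/response1/representation1")
    items = list(rg.graph.subject_objects(predicate=None))
    from lhr.namespaces import SEMREST

    data_items = set(rg.graph.objects(None, SEMREST.dataItem))
    assert len(data_items) == 3
    tags = set(rg.graph.objects(None, SEMREST.hasTag))
    assert tags == {rg.graph.namespace_manager.absolutize("https://schema.org/steps")}
    assert not rg.warnings


def test_semrest_ten_day_body_ten_items():
    body, context, _ = gen_fitbit_steps(n_days=10, seed=1)
    rg = parse_semrest(body, context, FITBIT_ROOT)
    from lhr.namespaces import SEMREST

    assert len(set(rg.graph.objects(None, SEMREST.dataItem))) == 10


def test_semrest_empty_body_and_bad_json():
    rg = parse_semrest("{}", '{"@context": {}}', FITBIT_ROOT)
    assert len(rg) == 0 and not rg.candidate_units
    with pytest.raises(MalformedDocumentError):
        parse_semrest("{not json", "{}", FITBIT_ROOT)
    with pytest.raises(MalformedDocumentError):
        parse_semrest("{}", "{not json", FITBIT_ROOT)


def test_semrest_unmapped_key_warning():
    body, context, _ = gen_fitbit_steps(n_days=1, seed=1)
    obj = json.loads(body)
    obj["unannotated_field"] = "boom"
    rg = parse_semrest(json.dumps(obj), context, FITBIT_ROOT)
    assert any("unmapped-key: unannotated_field" in w for w in rg.warnings)


def test_linked_data_prefix_filter():
    root = "https://data.example.org/health"
    doc = (
        f'<{root}/a> <https://p.example/p> "1" .\n'
        f'<{root}/b> <https://p.example/p> "2" .\n'
        '<https://elsewhere.example/c> <https://p.example/p> "3" .\n'
    )
    rg = parse_linked_data(doc, "turtle", root)
    assert len(rg.candidate_units) == 2
    assert all((u, RDF.type, LHR.LDResource) in rg.graph for u in rg.candidate_units)
    # external subject's triples retained
    assert len(rg) == 3 + 2
    all_external = parse_linked_data(
        '<https://elsewhere.example/c> <https://p.example/p> "3" .', "turtle", root
    )
    assert not all_external.candidate_units and len(all_external) == 1
    assert not parse_linked_data("", "turtle", root).candidate_units


def test_identify_units_excludes_scaffolding(axioms):
    body, context, _ = gen_fitbit_steps(n_days=3, seed=42)
    rg = parse_semrest(body, context, FITBIT_ROOT)
    units = identify_representation_units(rg, axioms)
    assert [str(u.node) for u in units] == [f"{FITBIT_ROOT}/steps/response1/representation1"]
    assert units[0].target_class == LHR.HealthResource
    # response node never reaches a target class: excluded
    assert all("response1/representation1" in str(u.node) for u in units)


def test_identify_units_across_merged_fixtures(axioms):
    fhir = parse_fhir_rdf(gen_fhir_observation(), "turtle", HEALTHCARE_ROOT)
    sosa = parse_sosa_rdf(gen_sosa_observations(), "turtle", WOT_ROOT, "env")
    fhir_units = identify_representation_units(fhir, axioms)
    sosa_units = identify_representation_units(sosa, axioms)
    assert len(fhir_units) == 1 and fhir_units[0].target_class == LHR.FHIRObservation
    assert len(sosa_units) == 2
    assert {u.target_class for u in sosa_units} == {LHR.EnvSSNResource}


def test_identify_units_empty_without_mappings(ontology):
    from lhr import extract_axioms

    bare = extract_axioms([ontology])  # no mapping extensions
    rg = parse_sosa_rdf(gen_sosa_observations(), "turtle", WOT_ROOT, "env")
    assert identify_representation_units(rg, bare) == []


def test_unit_selection_invariant_to_metadata_triples(axioms):
    doc = gen_fhir_observation()
    rg1 = parse_fhir_rdf(doc, "turtle", HEALTHCARE_ROOT)
    noisy = doc + "\n<https://noise.example/x> <https://noise.example/p> <https://noise.example/y> ."
    rg2 = parse_fhir_rdf(noisy, "turtle", HEALTHCARE_ROOT)
    u1 = [u.node for u in identify_representation_units(rg1, axioms)]
    u2 = [u.node for u in identify_representation_units(rg2, axioms)]
    assert u1 == u2


def test_jsonld_compaction_reproduces_key_set():
    """Compacting the expanded steps graph under its own context yields the
    original annotated keys."""
    body, context, _ = gen_fitbit_steps(n_days=2, seed=5)
    rg = parse_semrest(body, context, FITBIT_ROOT)
    ctx = json.loads(context)
    compacted = json.loads(rg.graph.serialize(format="json-ld", context=ctx["@context"]))
    text = json.dumps(compacted)
    for key in ("representation", "dataItem", "value", "date", "time", "tag"):
        assert f'"{key}"' in text
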