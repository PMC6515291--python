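"""Synthetic source documents for the integration pipeline.

No public test dataset exists for this kind of person-centric service
bundle, so every source document is generated here: a FHIR/RDF blood-glucose
observation (following the shape of the official FHIR observation example,
LOINC 15074-8, glucose in mmol/L), a Fitbit-style daily-steps Web-API
response annotated with a SemREST JSON-LD context, an SSN/SOSA document with
home temperature and humidity observations, and plain Linked Data documents.
All literal values are fixture choices; node URIs mirror the shapes real
services emit (``…/Observation/f001``, ``…/response1/representation1``).

Generation is fully deterministic under a seed, and parameterized bundles
carry analytically computed expected counts so pipeline output can be
checked against closed-form numbers.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from datetime import date as _date
from datetime import timedelta

from rdflib import URIRef

from .integrator import PersonRef
from .namespaces import LOINC, QUANTITYKIND, SCHEMA, SEMREST
from .ontology import MappingExtension, semrest_mapping_extension

#: Default service roots for the three-source personal-health scenario.
HEALTHCARE_ROOT = "https://healthcare.example.org/fhir"
FITBIT_ROOT = "https://fitbit.example.org"
WOT_ROOT = "https://home.example.org/wot"

GLUCOSE_CODE = LOINC["15074-8"]
STEPS_TAG = SCHEMA["steps"]


@dataclass
class SourceSpec:
    """One generated source document plus how to parse it."""

    document: str
    format: str  # "turtle" for RDF kinds, "json" for semrest bodies
    kind: str  # fhir-rdf | sosa-rdf | semrest-json | linked-data
    service_root: str
    polarity: str | None = None
    context: str | None = None  # JSON-LD context (semrest-json only)


@dataclass
class ScenarioBundle:
    """A person plus generated sources, mapping extensions and the counts
    the generation parameters imply."""

    person: PersonRef
    sources: list[SourceSpec]
    extensions: list[MappingExtension] | None
    expected_counts: dict = field(default_factory=dict)


def gen_fhir_observation(
    code_uri: str | URIRef = GLUCOSE_CODE,
    value: float = 6.3,
    unit_label: str = "mmol/l",
    effective: str = "2019-04-01T09:30:10+01:00",
    resource_id: str = "f001",
    service_root: str = HEALTHCARE_ROOT,
) -> str:
    """A simplified FHIR/RDF observation in Turtle: value quantity,
    effective date-time, and a terminology code naming the measurement."""
    return f"""@prefix fhir: <http://hl7.org/fhir/> .
@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .

<{service_root}/Observation/{resource_id}> a fhir:Observation ;
    fhir:Observation.status "final" ;
    fhir:Observation.code <{code_uri}> ;
    fhir:Observation.valueQuantity [
        a fhir:Quantity ;
        fhir:Quantity.value "{value}"^^xsd:decimal ;
        fhir:Quantity.unit "{unit_label}"
    ] ;
    fhir:Observation.effectiveDateTime "{effective}"^^xsd:dateTime .
"""


def gen_fitbit_steps(
    n_days: int = 3,
    start_date: _date = _date(2019, 4, 1),
    seed: int = 42,
    service_root: str = FITBIT_ROOT,
) -> tuple[str, str, MappingExtension]:
    """A Fitbit-style daily-steps response with its SemREST annotation.

    Returns ``(body_json, context_jsonld, mapping_extension)``.  The body
    holds one entry per day with a pseudo-random step count, the date, the
    recording time, and the schema.org steps term as a semantic tag; the
    extension is the SemREST→LHR mapping for the health configuration.
    """
    if n_days < 0:
        raise ValueError("n_days must be >= 0")
    rng = random.Random(seed)
    entries = []
    for i in range(n_days):
        day = start_date + timedelta(days=i)
        entries.append(
            {
                "value": rng.randint(2000, 18000),
                "date": day.isoformat(),
                "time": "23:59:00",
                "tag": str(STEPS_TAG),
            }
        )
    body = {
        "@id": f"{service_root}/steps/response1",
        "@type": "Response",
        "representation": {
            "@id": f"{service_root}/steps/response1/representation1",
            "@type": "Representation",
            "dataItem": entries,
        },
    }
    context = {
        "@context": {
            "semrest": str(SEMREST),
            "Response": "semrest:Response",
            "Representation": "semrest:Representation",
            "representation": {"@id": "semrest:representation", "@type": "@id"},
            "dataItem": "semrest:dataItem",
            "value": "semrest:hasValue",
            "date": "semrest:hasDate",
            "time": "semrest:hasTime",
            "tag": {"@id": "semrest:hasTag", "@type": "@id"},
        }
    }
    return (
        json.dumps(body, indent=2),
        json.dumps(context, indent=2),
        semrest_mapping_extension("health"),
    )


def gen_sosa_observations(
    props: list[tuple] | None = None,
    sensor_id: str = "dht22",
    service_root: str = WOT_ROOT,
) -> str:
    """An SSN/SOSA Turtle document: one ``sosa:Observation`` per entry of
    *props* ``(observed_property_uri, value, result_time)``, all made by one
    sensor hosted on one system."""
    if props is None:
        props = [
            (QUANTITYKIND.Temperature, 21.5, "2019-04-03T18:00:00+01:00"),
            (QUANTITYKIND.RelativeHumidity, 45.0, "2019-04-03T18:00:00+01:00"),
        ]
    sensor = f"{service_root}/sensor/{sensor_id}"
    lines = [
        "@prefix sosa: <http://www.w3.org/ns/sosa/> .",
        "@prefix ssn: <http://www.w3.org/ns/ssn/> .",
        "@prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .",
        "@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .",
        "",
        f"<{service_root}> a ssn:System ; ssn:hasSubSystem <{sensor}> .",
        f"<{sensor}> a sosa:Sensor .",
    ]
    for i, (prop, value, when) in enumerate(props, start=1):
        local = str(prop).rstrip("/#").rsplit("/", 1)[-1].rsplit("#", 1)[-1].lower()
        obs = f"{service_root}/obs/{local}-{i}"
        lines += [
            "",
            f"<{obs}> a sosa:Observation ;",
            f"    sosa:madeBySensor <{sensor}> ;",
            f"    sosa:observedProperty <{prop}> ;",
            f'    sosa:hasResult [ rdf:value "{value}"^^xsd:decimal ] ;',
            f'    sosa:resultTime "{when}"^^xsd:dateTime .',
            f"<{sensor}> sosa:madeObservation <{obs}> .",
        ]
    return "\n".join(lines) + "\n"


def gen_linked_data(
    n_subjects: int = 2, service_root: str = "https://data.example.org/health", seed: int = 0
) -> str:
    """A small Linked Data document with *n_subjects* subjects under the
    service root plus one external subject."""
    rng = random.Random(seed)
    lines = [
        "@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .",
        "@prefix dcterms: <http://purl.org/dc/terms/> .",
        "",
    ]
    for i in range(1, n_subjects + 1):
        lines.append(f'<{service_root}/entry/{i}> rdfs:label "open health fact {rng.randint(1, 999)}" ;')
        lines.append(f"    dcterms:references <https://other.example.net/topic/{i}> .")
    lines.append(f'<https://other.example.net/topic/0> rdfs:label "external" .')
    return "\n".join(lines) + "\n"


def gen_alice_scenario(seed: int = 7) -> ScenarioBundle:
    """The three-source personal-health scenario.

    Alice integrates one blood-glucose observation from a FHIR service,
    three days of step counts from a Fitbit-style annotated Web API, and a
    temperature plus a humidity observation from a home WoT device — two
    health units, two environment units, six data items in total.
    """
    person = PersonRef.mint("Alice")
    fhir_doc = gen_fhir_observation()
    body, context, semrest_ext = gen_fitbit_steps(n_days=3, seed=seed)
    sosa_doc = gen_sosa_observations()
    sources = [
        SourceSpec(fhir_doc, "turtle", "fhir-rdf", HEALTHCARE_ROOT),
        SourceSpec(body, "json", "semrest-json", FITBIT_ROOT, "health", context),
        SourceSpec(sosa_doc, "turtle", "sosa-rdf", WOT_ROOT, "env"),
    ]
    return ScenarioBundle(
        person=person,
        sources=sources,
        extensions=None,  # integrator falls back to the built-in extensions
        expected_counts={"health_units": 2, "env_units": 2, "data_items": 6},
    )


#: Data-bearing kinds used by default in random bundles; linked-data sources
#: carry no observation data and participate only when explicitly requested.
_DEFAULT_MIX = {"fhir-rdf": 1 / 3, "semrest-json": 1 / 3, "sosa-rdf": 1 / 3}


def _assign_kinds(n_services: int, mix: dict) -> list[str]:
    """Largest-remainder apportionment of service kinds — deterministic, so
    expected counts follow analytically from the parameters."""
    total = sum(mix.values())
    if total <= 0:
        raise ValueError("mix proportions must sum to a positive value")
    kinds = sorted(mix)
    quotas = {k: n_services * mix[k] / total for k in kinds}
    counts = {k: int(quotas[k]) for k in kinds}
    remainder = n_services - sum(counts.values())
    for k in sorted(kinds, key=lambda k: (-(quotas[k] - counts[k]), k))[:remainder]:
        counts[k] += 1
    out: list[str] = []
    for k in kinds:
        out += [k] * counts[k]
    return out


def gen_random_bundle(
    n_services: int,
    items_per_service: int,
    mix: dict | None = None,
    seed: int = 0,
) -> ScenarioBundle:
    """A reproducible bundle of *n_services* services mixing source kinds.

    ``expected_counts`` are computed analytically from the kind assignment:
    every fhir/semrest/sosa service contributes ``items_per_service`` data
    items (linked-data services contribute none); health units come from
    fhir and semrest services, environment units from sosa services.
    """
    if n_services < 0 or items_per_service < 0:
        raise ValueError("counts must be >= 0")
    mix = dict(mix) if mix else dict(_DEFAULT_MIX)
    kinds = _assign_kinds(n_services, mix)
    rng = random.Random(seed)
    person = PersonRef.mint(f"subject-{seed}")

    sources: list[SourceSpec] = []
    health_units = env_units = health_items = env_items = 0
    m = items_per_service
    for idx, kind in enumerate(kinds, start=1):
        if kind == "fhir-rdf":
            root = f"https://fhir{idx}.example.org/fhir"
            docs = [
                gen_fhir_observation(
                    value=round(rng.uniform(4.0, 9.0), 1),
                    effective=f"2019-04-{(j % 28) + 1:02d}T08:00:00+01:00",
                    resource_id=f"f{idx:03d}{j:03d}",
                    service_root=root,
                )
                for j in range(m)
            ]
            sources.append(SourceSpec("\n".join(docs), "turtle", "fhir-rdf", root))
            health_units += m
            health_items += m
        elif kind == "semrest-json":
            root = f"https://api{idx}.example.org"
            body, context, _ = gen_fitbit_steps(
                n_days=m, seed=seed * 1000 + idx, service_root=root
            )
            sources.append(SourceSpec(body, "json", "semrest-json", root, "health", context))
            health_units += 1
            health_items += m
        elif kind == "sosa-rdf":
            root = f"https://wot{idx}.example.org"
            props = [
                (
                    QUANTITYKIND.Temperature if j % 2 == 0 else QUANTITYKIND.RelativeHumidity,
                    round(rng.uniform(15.0, 60.0), 1),
                    f"2019-04-{(j % 28) + 1:02d}T18:00:00+01:00",
                )
                for j in range(m)
            ]
            sources.append(
                SourceSpec(gen_sosa_observations(props, service_root=root), "turtle", "sosa-rdf", root, "env")
            )
            env_units += m
            env_items += m
        elif kind == "linked-data":
            root = f"https://data{idx}.example.org/set"
            sources.append(
                SourceSpec(gen_linked_data(m, service_root=root, seed=seed + idx), "turtle", "linked-data", root)
            )
        else:
            raise ValueError(f"unknown source kind {kind!r}")

    return ScenarioBundle(
        person=person,
        sources=sources,
        extensions=None,
        expected_counts={
            "health_units": health_units,
            "env_units": env_units,
            "health_items": health_items,
            "env_items": env_items,
            "data_items": health_items + env_items,
        },
    )


def parse_bundle(bundle: ScenarioBundle):
    """Run every source of *bundle* through its adapter; returns the list of
    :class:`~lhr.adapters.ResourceGraph` objects in source order."""
    from . import adapters

    graphs = []
    for src in bundle.sources:
        if src.kind == "fhir-rdf":
            graphs.append(adapters.parse_fhir_rdf(src.document, src.format, src.service_root))
        elif src.kind == "sosa-rdf":
            graphs.append(
                adapters.parse_sosa_rdf(
                    src.document, src.format, src.service_root, src.polarity or "env"
                )
            )
        elif src.kind == "semrest-json":
            graphs.append(adapters.parse_semrest(src.document, src.context or "{}", src.service_root))
        elif src.kind == "linked-data":
            graphs.append(adapters.parse_linked_data(src.document, src.format, src.service_root))
        else:
            raise ValueError(f"unknown source kind {src.kind!r}")
    return graphs


def integrate_bundle(bundle: ScenarioBundle):
    """Parse and integrate a bundle in one step."""
    from .integrator import integrate

    return integrate(bundle.person, parse_bundle(bundle), bundle.extensions)
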