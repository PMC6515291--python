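"""Namespace table for the Linked Health Resource (LHR) vocabulary and the
external vocabularies it maps.

The LHR namespace itself is a minted example namespace; it can be swapped by
rebuilding the ontology with a different ``namespace`` argument, but every
module in this package defaults to :data:`LHR`.
"""

from __future__ import annotations

from rdflib import Graph, Namespace
from rdflib.namespace import OWL, RDF, RDFS, XSD

#: Default namespace for the LHR integration ontology (configurable constant).
LHR_NS = "https://example.org/lhr#"
LHR = Namespace(LHR_NS)

#: HL7 FHIR RDF vocabulary.
FHIR = Namespace("http://hl7.org/fhir/")

#: W3C Sensor, Observation, Sample, and Actuator ontology.
SOSA = Namespace("http://www.w3.org/ns/sosa/")

#: W3C Semantic Sensor Network ontology.
SSN = Namespace("http://www.w3.org/ns/ssn/")

#: Stand-in namespace for the SemREST annotation vocabulary.
SEMREST = Namespace("https://example.org/semrest#")

#: W3C Web of Things Thing Description vocabulary.
TD = Namespace("https://www.w3.org/2019/wot/td#")

#: schema.org, used for semantic tags on annotated Web-API data items.
SCHEMA = Namespace("https://schema.org/")

#: LOINC clinical terminology identifiers.
LOINC = Namespace("https://loinc.org/")

#: QUDT quantity kinds, used as value types for environment observations.
QUANTITYKIND = Namespace("http://qudt.org/vocab/quantitykind/")

_BINDINGS = {
    "lhr": LHR,
    "fhir": FHIR,
    "sosa": SOSA,
    "ssn": SSN,
    "semrest": SEMREST,
    "td": TD,
    "schema": SCHEMA,
    "loinc": LOINC,
    "quantitykind": QUANTITYKIND,
    "owl": OWL,
    "rdf": RDF,
    "rdfs": RDFS,
    "xsd": XSD,
}


def bind_namespaces(graph: Graph, lhr: Namespace = LHR) -> Graph:
    """Bind the package's prefix table onto *graph* and return it."""
    for prefix, ns in _BINDINGS.items():
        graph.bind(prefix, lhr if prefix == "lhr" else ns, override=True)
    return graph
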