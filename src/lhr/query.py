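"""SPARQL access to the integrated resource graph.

The graph is fully materialized by the integrator, so plain SPARQL 1.1
evaluation (no entailment regime) answers ontology-level questions.  Two
canned queries mirror the use-case retrievals: all of a person's health
resources, and all home-environment resources, each with the data value,
date-time and value type of every data item.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field

from rdflib import Graph, Literal, URIRef

from .errors import QueryParseError
from .integrator import IntegratedGraph
from .namespaces import LHR

_PREFIXES = f"PREFIX lhr: <{LHR}>\nPREFIX rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#>\n"

_CANNED_TEMPLATE = """{prefixes}
SELECT ?resource ?value ?datetime ?valueType
WHERE {{
  ?resource rdf:type {class_pattern} .
  ?resource lhr:hasObservationData ?d .
  ?d lhr:hasDataValue ?value .
  OPTIONAL {{ ?d lhr:hasObservationDateTime ?datetime }}
  OPTIONAL {{ ?d lhr:hasValueType ?valueType }}
  {person_clause}
}}
ORDER BY ?resource ?datetime
"""


@dataclass
class ResultRows:
    """SPARQL SELECT results with a deterministic row order."""

    variables: list[str]
    rows: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def column(self, name: str) -> list:
        return [row.get(name) for row in self.rows]

    def to_csv(self, delimiter: str = ",") -> str:
        buf = io.StringIO()
        writer = csv.writer(buf, delimiter=delimiter, lineterminator="\n")
        writer.writerow(self.variables)
        for row in self.rows:
            writer.writerow(["" if row.get(v) is None else str(row.get(v)) for v in self.variables])
        return buf.getvalue()

    def to_json(self) -> str:
        """SPARQL 1.1 Query Results JSON."""
        bindings = []
        for row in self.rows:
            b = {}
            for v in self.variables:
                term = row.get(v)
                if term is None:
                    continue
                if isinstance(term, URIRef):
                    b[v] = {"type": "uri", "value": str(term)}
                elif isinstance(term, Literal):
                    entry = {"type": "literal", "value": str(term)}
                    if term.datatype:
                        entry["datatype"] = str(term.datatype)
                    if term.language:
                        entry["xml:lang"] = term.language
                    b[v] = entry
                else:
                    b[v] = {"type": "bnode", "value": str(term)}
            bindings.append(b)
        return json.dumps(
            {"head": {"vars": self.variables}, "results": {"bindings": bindings}}, indent=2
        )


def run_query(graph: IntegratedGraph | Graph, sparql: str) -> ResultRows:
    """Evaluate a SPARQL SELECT over the materialized graph.

    Rows are sorted by the first projected variable (then the rest) unless
    the query itself orders them, making results reproducible.
    """
    g = graph.graph if isinstance(graph, IntegratedGraph) else graph
    try:
        result = g.query(sparql)
    except Exception as exc:
        raise QueryParseError(f"SPARQL query failed to parse: {exc}") from exc
    variables = [str(v) for v in (result.vars or [])]
    rows = [
        {v: row[i] for i, v in enumerate(variables) if row[i] is not None} for row in result
    ]
    rows.sort(key=lambda r: tuple(str(r.get(v, "")) for v in variables))
    return ResultRows(variables=variables, rows=rows)


def _canned(class_pattern: str, person: URIRef | None) -> str:
    person_clause = f"<{person}> lhr:hasResource ?resource ." if person else ""
    return _CANNED_TEMPLATE.format(
        prefixes=_PREFIXES, class_pattern=class_pattern, person_clause=person_clause
    )


def health_resources_query(person: URIRef | None = None) -> str:
    """A person's health resources with value, date-time and value type."""
    return _canned("lhr:HealthResource", person)


def env_resources_query(person: URIRef | None = None) -> str:
    """A person's home-environment resources with value, date-time, value type."""
    return _canned("lhr:EnvResource", person)


def combined_resources_query(person: URIRef | None = None) -> str:
    """Health and environment resources together, in a single query."""
    pattern = "?cls . VALUES ?cls { lhr:HealthResource lhr:EnvResource }"
    return _canned(pattern, person)
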