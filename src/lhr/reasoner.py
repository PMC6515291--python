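"""Lightweight forward-chaining inference over LHR data graphs.

The integration model only needs a small RDFS-plus rule profile — subclass
and subproperty propagation, one transitive object property, one inverse
pair, and domain/range typing.  That keeps materialization linear-ish and
lets a person's full resource graph close in milliseconds, with no OWL-DL
machinery.

Rules (least fixpoint over the data graph):

    (x rdf:type A)  &  A ⊑ B            ⇒  (x rdf:type B)
    (x p y)         &  p ⊑ q            ⇒  (x q y)
    (x p y), (y p z) &  p transitive    ⇒  (x p z)
    (x p y)         &  p owl:inverseOf q ⇒  (y q x)
    (x p y)         &  domain(p) = C     ⇒  (x rdf:type C)
    (x p y)         &  range(p)  = C     ⇒  (y rdf:type C)   [y not a literal]

The engine is semi-naive: each triple is processed once off a worklist and
only its one-step consequences are generated, which is equivalent to the
naive re-scan fixpoint because the axiom hierarchies are pre-closed
(reflexively and transitively) in :meth:`AxiomSet.normalize`.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS

from .namespaces import bind_namespaces

Triple = tuple

_AXIOM_PREDICATES = (
    RDFS.subClassOf,
    RDFS.subPropertyOf,
    OWL.equivalentClass,
    OWL.equivalentProperty,
    OWL.inverseOf,
    RDFS.domain,
    RDFS.range,
)


@dataclass
class AxiomSet:
    """Normalized schema axioms extracted from ontology + mapping graphs.

    ``subclass_pairs`` / ``subproperty_pairs`` hold the *closed* hierarchy
    (reflexive over mentioned terms, transitive, with equivalences expanded
    into two directed pairs).  ``inverse_pairs`` is symmetric.
    """

    subclass_pairs: set[tuple[URIRef, URIRef]] = field(default_factory=set)
    subproperty_pairs: set[tuple[URIRef, URIRef]] = field(default_factory=set)
    transitive_properties: set[URIRef] = field(default_factory=set)
    inverse_pairs: set[tuple[URIRef, URIRef]] = field(default_factory=set)
    domain_map: dict[URIRef, set[URIRef]] = field(default_factory=dict)
    range_map: dict[URIRef, set[URIRef]] = field(default_factory=dict)

    # --- derived lookup tables (built by normalize) -----------------------
    superclasses: dict[URIRef, set[URIRef]] = field(default_factory=dict, repr=False)
    superproperties: dict[URIRef, set[URIRef]] = field(default_factory=dict, repr=False)
    inverses: dict[URIRef, set[URIRef]] = field(default_factory=dict, repr=False)

    def normalize(self) -> "AxiomSet":
        """Close hierarchies reflexively + transitively and build lookups."""
        self.subclass_pairs = _reflexive_transitive_closure(self.subclass_pairs)
        self.subproperty_pairs = _reflexive_transitive_closure(self.subproperty_pairs)
        self.inverse_pairs |= {(b, a) for a, b in self.inverse_pairs}
        # Subproperties of transitive/inverse properties do not inherit those
        # characteristics in this profile; only the declared property chains.
        self.superclasses = _as_lookup(self.subclass_pairs)
        self.superproperties = _as_lookup(self.subproperty_pairs)
        self.inverses = _as_lookup(self.inverse_pairs)
        # Propagate domain/range up nothing; apply through superproperty rule
        # instead (a triple (x p y) also materializes (x q y) for q ⊒ p, and
        # q's domain/range then fire on that materialized triple).
        return self

    def without_transitivity(self) -> "AxiomSet":
        """Copy with no transitive properties (negative-control reasoning)."""
        clone = AxiomSet(
            subclass_pairs=set(self.subclass_pairs),
            subproperty_pairs=set(self.subproperty_pairs),
            transitive_properties=set(),
            inverse_pairs=set(self.inverse_pairs),
            domain_map={k: set(v) for k, v in self.domain_map.items()},
            range_map={k: set(v) for k, v in self.range_map.items()},
        )
        return clone.normalize()


def _reflexive_transitive_closure(pairs: set[tuple]) -> set[tuple]:
    closure = set(pairs)
    terms = {t for pair in pairs for t in pair}
    closure |= {(t, t) for t in terms}
    changed = True
    succ: dict = {}
    while changed:
        changed = False
        succ.clear()
        for a, b in closure:
            succ.setdefault(a, set()).add(b)
        for a, b in list(closure):
            for c in succ.get(b, ()):
                if (a, c) not in closure:
                    closure.add((a, c))
                    changed = True
    return closure


def _as_lookup(pairs: Iterable[tuple]) -> dict:
    table: dict = {}
    for a, b in pairs:
        table.setdefault(a, set()).add(b)
    return table


def extract_axioms(graphs: Iterable) -> AxiomSet:
    """Collect schema axioms from ontology graphs and mapping extensions.

    Accepts :class:`rdflib.Graph` objects and anything with a ``.graph``
    attribute (e.g. :class:`~lhr.ontology.MappingExtension`).  Every
    rdfs:subClassOf / rdfs:subPropertyOf / owl:equivalentClass (two pairs) /
    owl:equivalentProperty (two pairs) / owl:TransitiveProperty /
    owl:inverseOf / rdfs:domain / rdfs:range statement is collected; all
    other triples are ignored.  The result is normalized.
    """
    ax = AxiomSet()
    for g in graphs:
        graph = getattr(g, "graph", g)
        for s, p, o in graph:
            if p == RDFS.subClassOf:
                ax.subclass_pairs.add((s, o))
            elif p == RDFS.subPropertyOf:
                ax.subproperty_pairs.add((s, o))
            elif p == OWL.equivalentClass:
                ax.subclass_pairs.add((s, o))
                ax.subclass_pairs.add((o, s))
            elif p == OWL.equivalentProperty:
                ax.subproperty_pairs.add((s, o))
                ax.subproperty_pairs.add((o, s))
            elif p == OWL.inverseOf:
                ax.inverse_pairs.add((s, o))
            elif p == RDF.type and o == OWL.TransitiveProperty:
                ax.transitive_properties.add(s)
            elif p == RDFS.domain:
                ax.domain_map.setdefault(s, set()).add(o)
            elif p == RDFS.range:
                ax.range_map.setdefault(s, set()).add(o)
    return ax.normalize()


@dataclass
class ClosedGraph:
    """A data graph materialized to its forward-chaining fixpoint.

    ``asserted`` are the input triples, ``inferred`` the triples the rules
    added; ``triples`` is their union.  The provenance split lets writers
    emit an asserted-only core that re-closes to the same graph.
    """

    asserted: set[Triple]
    inferred: set[Triple]
    axioms: AxiomSet

    @property
    def triples(self) -> set[Triple]:
        return self.asserted | self.inferred

    def __len__(self) -> int:
        return len(self.asserted) + len(self.inferred)

    def __contains__(self, triple: Triple) -> bool:
        return triple in self.asserted or triple in self.inferred

    def to_graph(self, asserted_only: bool = False) -> Graph:
        g = bind_namespaces(Graph())
        triples = self.asserted if asserted_only else self.triples
        # insertion order fixed so serializations are stable across runs
        for t in sorted(triples, key=lambda t: (str(t[0]), str(t[1]), str(t[2]))):
            g.add(t)
        return g


def forward_chain(data, axioms: AxiomSet) -> ClosedGraph:
    """Materialize the least fixpoint of *data* under the rule profile.

    *data* may be an :class:`rdflib.Graph`, an iterable of triples, or a
    :class:`ClosedGraph` (re-closing is idempotent).
    """
    if isinstance(data, ClosedGraph):
        asserted = set(data.asserted)
        seed = data.triples
    else:
        asserted = set(getattr(data, "graph", data))
        seed = asserted

    closure: set[Triple] = set()
    # join indexes for the transitivity rule: (p, s) -> objects, (p, o) -> subjects
    by_ps: dict[tuple, set] = {}
    by_po: dict[tuple, set] = {}
    todo: deque[Triple] = deque()

    def add(t: Triple) -> None:
        if t not in closure:
            closure.add(t)
            todo.append(t)
            s, p, o = t
            by_ps.setdefault((p, s), set()).add(o)
            by_po.setdefault((p, o), set()).add(s)

    for t in sorted(seed, key=lambda t: (str(t[0]), str(t[1]), str(t[2]))):
        add(t)

    sup_c = axioms.superclasses
    sup_p = axioms.superproperties
    inv = axioms.inverses
    dom = axioms.domain_map
    rng = axioms.range_map
    trans = axioms.transitive_properties

    while todo:
        s, p, o = todo.popleft()
        if p == RDF.type and not isinstance(o, Literal):
            for b in sup_c.get(o, ()):
                add((s, RDF.type, b))
        for q in sup_p.get(p, ()):
            if q != p:
                add((s, q, o))
        if p in trans:
            for z in tuple(by_ps.get((p, o), ())):
                add((s, p, z))
            for x in tuple(by_po.get((p, s), ())):
                add((x, p, o))
        for q in inv.get(p, ()):
            if not isinstance(o, Literal):
                add((o, q, s))
        for c in dom.get(p, ()):
            add((s, RDF.type, c))
        if not isinstance(o, Literal):
            for c in rng.get(p, ()):
                add((o, RDF.type, c))

    return ClosedGraph(asserted=asserted, inferred=closure - asserted, axioms=axioms)


def entails(graph: ClosedGraph, triple: Triple) -> bool:
    """True iff *triple* is in the materialized closure."""
    return triple in graph
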