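"""Independent brute-force closure oracle and random-instance generator.

The oracle re-scans the whole graph against the raw (un-normalized) axiom
statements until nothing changes.  It shares no code with the semi-naive
engine in ``lhr.reasoner`` — rule semantics are re-derived directly from the
axiom triples — so set-equality of the two closures is a meaningful check.
"""

from __future__ import annotations

import random

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS


def naive_closure(data_triples, axiom_graph: Graph) -> set:
    """Least fixpoint by naive re-scanning of every rule on every triple."""
    subclass = set()
    subprop = set()
    transitive = set()
    inverse = set()
    domain = []
    range_ = []
    for s, p, o in axiom_graph:
        if p == RDFS.subClassOf:
            subclass.add((s, o))
        elif p == OWL.equivalentClass:
            subclass.add((s, o))
            subclass.add((o, s))
        elif p == RDFS.subPropertyOf:
            subprop.add((s, o))
        elif p == OWL.equivalentProperty:
            subprop.add((s, o))
            subprop.add((o, s))
        elif p == RDF.type and o == OWL.TransitiveProperty:
            transitive.add(s)
        elif p == OWL.inverseOf:
            inverse.add((s, o))
            inverse.add((o, s))
        elif p == RDFS.domain:
            domain.append((s, o))
        elif p == RDFS.range:
            range_.append((s, o))

    closure = set(data_triples)
    while True:
        new = set()
        for s, p, o in closure:
            if p == RDF.type:
                for a, b in subclass:
                    if o == a:
                        new.add((s, RDF.type, b))
            for a, b in subprop:
                if p == a:
                    new.add((s, b, o))
            if p in transitive:
                for s2, p2, o2 in closure:
                    if p2 == p and s2 == o:
                        new.add((s, p, o2))
                    if p2 == p and o2 == s:
                        new.add((s2, p, o))
            for a, b in inverse:
                if p == a and not isinstance(o, Literal):
                    new.add((o, b, s))
            for a, c in domain:
                if p == a:
                    new.add((s, RDF.type, c))
            for a, c in range_:
                if p == a and not isinstance(o, Literal):
                    new.add((o, RDF.type, c))
        if new <= closure:
            return closure
        closure |= new


EX = "https://example.org/rand/"
NODES = [URIRef(EX + f"n{i}") for i in range(8)]
PROPS = [URIRef(EX + f"p{i}") for i in range(4)]
CLASSES = [URIRef(EX + f"C{i}") for i in range(4)]


def random_instance(seed: int, max_triples: int = 50, max_axioms: int = 12):
    """A random small data graph + schema graph over a fixed vocabulary."""
    rng = random.Random(seed)
    data = set()
    for _ in range(rng.randint(0, max_triples)):
        s = rng.choice(NODES)
        if rng.random() < 0.3:
            data.add((s, RDF.type, rng.choice(CLASSES)))
        else:
            o = rng.choice(NODES) if rng.random() < 0.8 else Literal(rng.randint(0, 9))
            data.add((s, rng.choice(PROPS), o))

    schema = Graph()
    for _ in range(rng.randint(0, max_axioms)):
        kind = rng.randrange(8)
        if kind == 0:
            schema.add((rng.choice(CLASSES), RDFS.subClassOf, rng.choice(CLASSES)))
        elif kind == 1:
            schema.add((rng.choice(CLASSES), OWL.equivalentClass, rng.choice(CLASSES)))
        elif kind == 2:
            schema.add((rng.choice(PROPS), RDFS.subPropertyOf, rng.choice(PROPS)))
        elif kind == 3:
            schema.add((rng.choice(PROPS), OWL.equivalentProperty, rng.choice(PROPS)))
        elif kind == 4:
            schema.add((rng.choice(PROPS), RDF.type, OWL.TransitiveProperty))
        elif kind == 5:
            schema.add((rng.choice(PROPS), OWL.inverseOf, rng.choice(PROPS)))
        elif kind == 6:
            schema.add((rng.choice(PROPS), RDFS.domain, rng.choice(CLASSES)))
        else:
            schema.add((rng.choice(PROPS), RDFS.range, rng.choice(CLASSES)))
    return data, schema
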