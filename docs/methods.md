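# Methods

## The integration model

`lhr` integrates personal health data and home-environment data from
heterogeneously built services into one RDF resource graph, rooted at the
person who owns the data. The model rests on a REST-flavoured reading of
the Web: anything identified by an HTTP URI is a *resource*; the resource at
the root path of a service's URI is the *service*; and a person, owning
services, is a resource too. Writing S_i for a service and R_j for the
resources it serves, a person's graph is

    G(P_k) = Σ_i S_i = Σ_i Σ_j R_ij ,

with each resource a tuple (D_r, R_link, T_r) of data items, interlinked
resources, and semantic tags.

Four source categories are supported, matching the interoperability levels
found in practice:

1. **FHIR services** — HL7 FHIR resources in their RDF (Turtle) form;
   `fhir:Observation` instances are the integrable content.
2. **Ontology-described WoT devices** — SSN/SOSA observation graphs.
3. **Ordinary Web/WoT APIs** — plain JSON responses made semantic by a
   JSON-LD context (the SemREST annotation style); the annotated
   *representation* node inside the response is the integrable unit.
4. **Linked Data** — RDF documents whose subjects under the service root
   are taken as generic `lhr:LDResource` instances.

### The LHR ontology

All integrated content is typed under one OWL/RDFS vocabulary:
`lhr:Person`, `lhr:Service`, `lhr:HealthResource`, `lhr:EnvResource` and
`lhr:LDResource` are subclasses of `lhr:Resource`; `lhr:FHIRObservation`
and `lhr:HealthSSNResource` specialize `lhr:HealthResource`, and
`lhr:EnvSSNResource` specializes `lhr:EnvResource`. Ownership is the
**transitive** object property `lhr:hasResource` (inverse:
`lhr:isResourceOf`), with subproperties `lhr:hasHealthResource`,
`lhr:hasLDResource` and `lhr:hasInterLinkedResource` carrying domain/range
constraints. Data payloads hang off resources through
`lhr:hasObservationData ⊑ lhr:hasDataItem`, into which each source idiom
funnels (`lhr:hasFHIRObservation.valueQuantity` and
`lhr:hasSOSAObservationResult` are its subproperties); items carry
`lhr:hasDataValue`, `lhr:hasObservationDateTime` and a `lhr:hasValueType`
URI (a LOINC code, a QUDT quantity kind, a schema.org term) naming what the
value means.

External vocabularies attach through *mapping extensions*: RDF
micro-documents restricted to `rdfs:subClassOf`, `rdfs:subPropertyOf`,
`owl:equivalentClass` and `owl:equivalentProperty`, one side of each axiom
in the LHR namespace. Built-ins cover FHIR
(`fhir:Observation ≡ lhr:FHIRObservation`), SSN/SOSA
(`sosa:Observation ≡ lhr:EnvSSNResource` or `lhr:HealthSSNResource`
depending on whether the device reports environment or health data),
SemREST and WoT Thing Description. Date-time mappings
(`fhir:Observation.effectiveDateTime`, `sosa:resultTime` →
`lhr:hasObservationDateTime`) are deliberately subproperty axioms rather
than equivalences: two source properties mapping onto the same LHR property
must not become equivalent to each other.

The LHR namespace itself is a minted, configurable constant
(`https://example.org/lhr#`); nothing else in the model depends on its
spelling.

### Inference

The ontology is engineered so that everything the integration needs follows
from a small RDFS-plus rule profile — subclass/subproperty propagation, one
transitive property, one inverse pair, domain/range typing — computed as a
materialized forward-chaining fixpoint. There is no owl:sameAs handling, no
restriction/cardinality reasoning, and no datatype entailment; the range
rule never types literals. Equivalences are normalized to two directed
subclass/subproperty pairs, and hierarchies are closed
reflexively-transitively up front, so the engine can process each triple
exactly once off a worklist (semi-naive evaluation) and still reach the
same fixpoint as naive re-scanning. The test suite keeps an independent
naive re-scan oracle and checks set-equality of the two closures on
hundreds of random instances; materialization is idempotent, monotone in
the data, and independent of input triple order. A worst-case bound of
|nodes|²·|properties| + |nodes|·|classes| triples guarantees termination.

Transitive or inverse *characteristics* do not propagate to subproperties
in this profile (only the triples do); none of the supported mappings needs
that inheritance.

### Pipeline

Per source, an adapter parses the representation, canonicalizes blank-node
labels (RGDA1) and skolemizes them under
`<service_root>/.well-known/genid/<sha1>` — deterministic across parses and
collision-free across services, so merged graphs are stable. The
*representation units* of a source are the nodes whose (possibly inferred)
type reaches `lhr:HealthResource`, `lhr:EnvResource` or `lhr:LDResource`
through the subclass closure; request/response scaffolding never reaches
those classes and is left behind.

The integrator then asserts the person/service scaffolding
(`person —hasResource→ service —hasResource→ unit`, so person-to-unit
reachability is exactly one transitivity application), types SOSA units per
the source's env/health polarity flag, and materializes the canonical
data-item triples for each idiom: FHIR value-quantity nodes get their
numeric value, the observation's effective date-time and its terminology
code; SOSA result nodes get `rdf:value`, `sosa:resultTime` and the observed
property; SemREST items get their annotated value, tag, and a fused
ISO-8601 date-time (separate date and time literals are joined; midnight is
assumed and flagged when the time is absent). Units of measure are *not*
normalized into data items — context of that kind is acknowledged as lossy
in this model, and the untouched source triples stay in the graph for
lookup. Provenance uses `unit lhr:isResourceOf service` links in a single
default graph rather than named graphs, keeping the result one resource
graph.

The merged graph is closed and served to SPARQL 1.1 SELECT directly (the
closure is materialized, so no entailment-aware engine is needed). Two
canned queries retrieve a person's health resources and home-environment
resources with value, date-time and value type; both use OPTIONAL for
date-time and value type so degraded items still surface, and accept an
optional person constraint. Their union equals the combined two-class
query.

## Synthetic sources

No public fixture exists for a person-centric bundle of this shape, so the
`fixtures` module generates one. The three-source scenario mirrors a
realistic self-management setting: one blood-glucose FHIR observation
shaped after the official FHIR observation example (LOINC 15074-8,
6.3 mmol/L — the value is a fixture choice), three days of step counts as
an annotated Fitbit-style JSON response whose representation node ends
`/response1/representation1`, and one temperature plus one humidity SOSA
observation (QUDT quantity kinds as observed properties). That yields 2
health units, 2 environment units and 6 data items. Step counts are drawn
uniformly from 2 000–18 000 per day, seeded; all generation is
deterministic under the seed.

`gen_random_bundle(n_services, items_per_service, mix, seed)` builds larger
bundles for property testing. Kinds are apportioned from the mix by largest
remainder — deterministically, so the expected unit and item counts follow
in closed form from the parameters: every FHIR/SemREST/SOSA service
contributes `items_per_service` data items; Linked Data sources contribute
units but no data items and are therefore excluded from the default mix.

What the generator does *not* emulate: real Fitbit/FHIR payload schemas in
full (only the structurally relevant subset), authentication and live
retrieval, conflicting or duplicated observations across services, units of
measure beyond a label, and time zones more adversarial than fixed offsets.
Passing tests show the integration and inference machinery is correct on
well-formed representative inputs, not that arbitrary real-world payloads
map cleanly.

## Numerical and design choices

- **Determinism**: graphs serialize from sorted triple order; canonical
  output is sorted N-Triples. Pipeline output is byte-identical across
  runs and hash seeds.
- **Degenerate inputs**: empty documents parse to empty graphs; an
  observation without a result/value yields a data item with a null value
  plus a warning, never an exception; unmapped JSON keys are dropped with a
  warning.
- **Dual typing** is permitted (no disjointness between health and
  environment branches); a bundle mixing both SOSA polarities loads both
  equivalence variants and the affected observations type into both
  branches.
- **Problem sizes** in the test and acceptance runs — 200 random reasoner
  instances of ≤50 triples/≤12 axioms, count sweeps up to 8 services × 5
  items — were chosen so the whole suite completes in seconds while still
  exercising every rule interaction; closures here are small enough that
  larger sizes add no new structure.

## Known limitations

- Only `fhir:Observation` among FHIR's clinical resources is mapped;
  other resource types are extension points via mapping extensions.
- The SemREST vocabulary has no canonical published namespace here; a
  stand-in (`https://example.org/semrest#`) is used and documented.
- No record linkage or temporal deduplication: the same real-world
  observation served by two services appears twice.
- No SPARQL UPDATE, federation or HTTP endpoint; querying is in-process.
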