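# lhr — Linked Health Resource integration

`lhr` integrates personal health data and home-environment data from
heterogeneously built services — HL7 FHIR servers, SSN/SOSA-described WoT
devices, ordinary Web APIs with JSON-LD semantic annotations, and Linked
Data — into a single person-rooted RDF resource graph that can be queried
with SPARQL. It is aimed at health-informatics developers building
self-management or monitoring applications on top of data silos that will
not converge on one interoperability standard any time soon.

The core idea: model everything as resources. With S_i a service serving
resources R_j, a person P_k's integrated graph is

    G(P_k) = Σ_i S_i = Σ_i Σ_j R_ij ,   R_j = (D_r, R_link, T_r)

where each resource carries data items D_r, links R_link and semantic tags
T_r. A compact OWL/RDFS ontology (classes `lhr:Person`, `lhr:Service`,
`lhr:HealthResource`, `lhr:EnvResource`, `lhr:LDResource`, …; the
transitive property `lhr:hasResource`) types all of it, and small *mapping
extensions* (subclass/subproperty/equivalence axioms) bind external
vocabularies — `fhir:Observation ≡ lhr:FHIRObservation`,
`sosa:Observation ≡ lhr:EnvSSNResource`, etc. — into the model. A built-in
forward-chaining reasoner (RDFS subclass/subproperty + transitivity +
inverse + domain/range) materializes the closure, after which one
transitivity step links the person to every integrated resource and plain
SPARQL answers ontology-level questions. See `docs/methods.md` for the full
account.

## Worked example

```python
from lhr import (
    fixtures, integrate_bundle, extract_data_items,
    health_resources_query, env_resources_query, run_query,
)

bundle = fixtures.gen_alice_scenario(seed=7)   # FHIR glucose + Fitbit steps + WoT climate
graph = integrate_bundle(bundle)

print(len(graph.units))                         # 4 representation units
items, _ = extract_data_items(graph)
print(len(items))                               # 6 data items
for row in run_query(graph, health_resources_query()).rows:
    print(str(row["resource"]), str(row["value"]), str(row["datetime"]))
```

prints:

```
4
6
https://fitbit.example.org/steps/response1/representation1 17529 2019-04-02T23:59:00
https://fitbit.example.org/steps/response1/representation1 4471 2019-04-03T23:59:00
https://fitbit.example.org/steps/response1/representation1 7305 2019-04-01T23:59:00
https://healthcare.example.org/fhir/Observation/f001 6.3 2019-04-01T09:30:10+01:00
```

The health query retrieves both the FHIR blood-glucose observation
(`…/Observation/f001`, reached through the subclass mapping of
`fhir:Observation`) and the Fitbit daily-steps representation node
(`…/response1/representation1`, typed `lhr:HealthResource` by its SemREST
mapping extension) — four rows because the steps resource carries three
daily data items. The value column is each item's measurement (steps per
day, mmol/L of glucose); the third column its ISO-8601 timestamp. The
analogous `env_resources_query()` returns the temperature and humidity
observations from the WoT device, and both classes can be retrieved in one
combined query.

The same pipeline runs from the shell:

```bash
lhr fixtures --scenario alice -o demo/          # generate sources + manifest
lhr integrate --manifest demo/manifest.yaml     # parse → integrate → close → write
lhr query demo/integrated.ttl --canned health   # CSV of resource,value,datetime,valueType
lhr build-ontology -o lhr.ttl                   # the ontology itself
lhr validate demo/mapping-fhir.ttl              # check a mapping extension
```

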