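import pytest

from lhr import (
    build_lhr_ontology,
    builtin_mapping_extensions,
    extract_axioms,
    extract_data_items,
    gen_alice_scenario,
    integrate_bundle,
    parse_bundle,
)


@pytest.fixture(scope="session")
def ontology():
    return build_lhr_ontology()


@pytest.fixture(scope="session")
def extensions():
    return builtin_mapping_extensions()


@pytest.fixture(scope="session")
def axioms(ontology, extensions):
    return extract_axioms([ontology, *extensions])


@pytest.fixture(scope="session")
def alice_bundle():
    return gen_alice_scenario(seed=7)


@pytest.fixture(scope="session")
def alice_sources(alice_bundle):
    return parse_bundle(alice_bundle)


@pytest.fixture(scope="session")
def alice_graph(alice_bundle):
    return integrate_bundle(alice_bundle)


@pytest.fixture(scope="session")
def alice_items(alice_graph):
    items, _ = extract_data_items(alice_graph)
    return items
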