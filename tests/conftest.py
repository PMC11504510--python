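import pytest

from nppm import assess, default_ruleset, generate_fixture


@pytest.fixture(scope="session")
def rules():
    return default_ruleset()


@pytest.fixture(scope="session")
def fixture_products(rules):
    return generate_fixture(rules)


@pytest.fixture(scope="session")
def fixture_assessments(fixture_products, rules):
    return assess(fixture_products, rules)
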