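import pytest

from genemeta import GeneticModel, bundled_fixture


@pytest.fixture(scope="session")
def fixture_table():
    return bundled_fixture()


@pytest.fixture(scope="session")
def fixture_by_id(fixture_table):
    return {r.study_id: r for r in fixture_table}


ALL_MODELS = tuple(GeneticModel)
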