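import pytest

from cephvig import (
    count_by_category,
    default_catalog,
    reserve_fixture,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def fixture_config():
    return reserve_fixture(seed=7)


@pytest.fixture(scope="session")
def fixture_reports(fixture_config, catalog):
    return simulate_dataset(fixture_config, catalog)


@pytest.fixture(scope="session")
def fixture_counts(fixture_reports, catalog):
    return count_by_category(fixture_reports, catalog)


@pytest.fixture(scope="session")
def counts_by_drug(fixture_counts):
    return {c.drug: c for c in fixture_counts}
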