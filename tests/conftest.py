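import pytest

from glycotrial.cohort import (
    CohortConfig,
    generate_cohort,
    generate_completions,
    generate_registry,
    generate_theme_catalog,
)


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_participants=60, n_registry=400, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_registry(small_config):
    return generate_registry(small_config)


@pytest.fixture(scope="session")
def catalog():
    return generate_theme_catalog(7)


@pytest.fixture(scope="session")
def completions(small_cohort, catalog, small_config):
    participants, series = small_cohort
    return generate_completions(participants, series, catalog, small_config)
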