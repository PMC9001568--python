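import pytest

from fracturecost import (
    GeneratorConfig,
    build_cohort,
    make_filter_fixture,
    simulate_population,
)


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated population with defaults (deaths included)."""
    cfg = GeneratorConfig(n_individuals=1200, seed=20140401)
    bundle, truth = simulate_population(cfg)
    return cfg, bundle, truth


@pytest.fixture(scope="session")
def small_cohort(small_sim):
    cfg, bundle, truth = small_sim
    cohort, exclusions = build_cohort(bundle, cfg.index_window)
    return cohort, exclusions


@pytest.fixture(scope="session")
def filter_fixture():
    return make_filter_fixture()
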