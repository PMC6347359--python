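import pytest

from synletcombo import (
    SyntheticWorldConfig,
    fixture_fig3,
    generate_world,
    run_classifier_benchmark,
)


@pytest.fixture(scope="session")
def fig3():
    """The fixed tested-combination worked example (drugs, combos, SL set)."""
    return fixture_fig3()


@pytest.fixture(scope="session")
def default_world():
    """One small generated world (200 genes / 40 SL pairs), seed 1."""
    return generate_world(SyntheticWorldConfig(seed=1))


@pytest.fixture(scope="session")
def default_benchmark():
    """Classifier benchmark on the small planted-signal world, seed 1."""
    return run_classifier_benchmark(SyntheticWorldConfig(seed=1))
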