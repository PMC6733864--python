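import numpy as np
import pytest

from dysbiome.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small healthy-vs-disease cohort with planted effects."""
    cfg = SimulationConfig(n_samples_per_group=30, n_otus=100, n_genera=10,
                           antibiotic_effect_log2fc=0.0, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no planted effects of any kind."""
    cfg = SimulationConfig(n_samples_per_group=30, n_otus=100, n_genera=10,
                           effect_log2fc=0.0, antibiotic_effect_log2fc=0.0,
                           seed=7)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
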