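import numpy as np
import pytest

import twocolor as tc


@pytest.fixture(scope="session")
def factorial_design():
    """Cell-line-like layout: 2 units x 4 treatments x 2 replicate sets."""
    return tc.make_design("factorial-replicated", n_groups=4, n_units_per_group=2,
                          technical_replicates=2)


@pytest.fixture(scope="session")
def paired_design():
    """Reference-benchmark layout: 10 arrays each co-hybridizing both groups."""
    return tc.make_design("two-group-paired", technical_replicates=10)


@pytest.fixture(scope="session")
def loop_design():
    """Cohort-like layout: 7 groups x 7 subjects chained around a loop."""
    return tc.make_design("interwoven-loop", n_groups=7, n_units_per_group=7)


@pytest.fixture(scope="session")
def paired_dataset():
    """Small simulated paired dataset with differential signal."""
    cfg = tc.SimulationConfig(
        seed=101, n_probes=400, topology="two-group-paired", technical_replicates=8,
        fraction_de=0.3, effect_sd=0.6, sigma_noise=0.25, sigma_array=0.1,
    )
    return tc.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def factorial_dataset():
    """Simulated replicated factorial (no biological variation)."""
    cfg = tc.SimulationConfig(
        seed=202, n_probes=600, topology="factorial-replicated", n_groups=4,
        n_units_per_group=2, technical_replicates=2, fraction_de=0.3,
        effect_sd=0.6, sigma_noise=0.25, sigma_array=0.1, sigma_unit=0.0,
    )
    return tc.simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
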