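import numpy as np
import pytest

import quasiumi as q


@pytest.fixture(scope="session")
def small_sim():
    """A 2000-gene x 30-cell Poisson-lognormal UMI simulation, shape 2."""
    return q.simulate_umi(q.SimulationConfig(n_genes=2000, n_cells=30, seed=11))


@pytest.fixture(scope="session")
def small_reads(small_sim):
    """PCR-amplified read counts matched to ``small_sim``."""
    return q.amplify_reads(small_sim.umi, amp_mean=50.0, amp_sd_log=1.0, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
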