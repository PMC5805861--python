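import numpy as np
import pytest

from genestrat.synthetic_cohort import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_synth():
    """A modest synthetic cohort shared by read-only tests."""
    return simulate_cohort(SimulationConfig(n_individuals=30_000, rng_seed=7))


@pytest.fixture(scope="session")
def small_stratified(small_synth):
    from genestrat.grs import compute_grs
    from genestrat.survival import split_by_median

    scores = compute_grs(small_synth.genotypes, small_synth.weights)
    return split_by_median(scores, small_synth.cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
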