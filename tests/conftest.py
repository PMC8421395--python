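import numpy as np
import pytest

from nuctail import synthetic as syn


@pytest.fixture(scope="session")
def toy():
    """Shared toy nucleosome (geometry is deterministic)."""
    return syn.build_toy_nucleosome()


@pytest.fixture(scope="session")
def small_ensemble(toy):
    """Two short kinetic runs on the toy nucleosome, with ground truth."""
    ensemble, sims = syn.toy_kinetic_ensemble(
        toy, n_runs=2, total_time=120.0, k_on=0.05, k_off=0.02, seed=11
    )
    return ensemble, sims


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
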