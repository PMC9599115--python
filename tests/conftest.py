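import numpy as np
import pytest
from hypothesis import settings

from spnplast import morphology as mo
from spnplast import spiketrains as st

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def morph():
    return mo.build_default_morphology()


@pytest.fixture(scope="session")
def spines(morph):
    return mo.place_spines(morph, 1.0, 25.0, seed=0)


@pytest.fixture(scope="session")
def dense_spines(morph):
    return mo.place_spines(morph, 2.0, 25.0, seed=1)


@pytest.fixture(scope="session")
def small_trial():
    """50 correlated trains over one 1 s trial."""
    spec = st.default_ensemble_spec(n_trains=50, seed=11)
    return st.generate_correlated_trains(spec)


def random_trains(rng, n_trains=5, n_max=30, duration=1.0):
    out = []
    for i in range(n_trains):
        n = rng.integers(0, n_max)
        times = np.unique(rng.uniform(0, duration, size=n))
        out.append(st.SpikeTrain(i, times, 0.0, duration))
    return out
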