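import numpy as np
import pytest

from recortex.synthetic import (
    CohortGenParams,
    SensoryGenParams,
    gen_behavior_cohort,
    gen_sensory_session,
)


@pytest.fixture(scope="session")
def small_sensory():
    """A 20-neuron tactile session (half responsive) with ground truth."""
    params = SensoryGenParams(seed=7, n_neurons=20, evoked_magnitude=3.0)
    session, truth = gen_sensory_session(params)
    return session, truth, params


@pytest.fixture(scope="session")
def cohort():
    return gen_behavior_cohort(CohortGenParams(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def brute_force_psth(spikes, events, window_ms, binsize_ms):
    """Independent nested-loop PSTH oracle."""
    lo, hi = window_ms
    n_bins = int(round((hi - lo) / binsize_ms))
    counts = np.zeros(n_bins, dtype=int)
    for ev in events:
        for t in spikes:
            rel = (t - ev) * 1000.0
            if lo <= rel < hi:
                b = int(np.floor((rel - lo) / binsize_ms))
                if b == n_bins:  # guard float edge
                    continue
                counts[b] += 1
    return counts


@pytest.fixture(scope="session")
def brute_psth():
    return brute_force_psth
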