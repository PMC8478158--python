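"""Shared fixtures: small synthetic experiments reused across test modules."""

import numpy as np
import pytest

from ddrcyto.pipeline import analyze_donor
from ddrcyto.synthetic_data import default_config_healthy, simulate_experiment


@pytest.fixture(scope="session")
def small_config():
    """A compact healthy experiment: 3 donors, 5 time points, 2,500 events each."""
    return default_config_healthy(n_donors=3, events_per_timepoint=2500, seed=11)


@pytest.fixture(scope="session")
def small_donors(small_config):
    return simulate_experiment(small_config)


@pytest.fixture(scope="session")
def analyzed_samples(small_donors):
    samples = []
    for d in small_donors:
        samples += analyze_donor(d.frame, d.scheme, d.manifest)
    return samples


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
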