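import numpy as np
import pytest
from hypothesis import settings

import dyadspeech as ds

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_session():
    """One simulated interview session (timeline, tracks, ground truth)."""
    return ds.simulate_session(ds.DyadSimConfig(seed=42))


@pytest.fixture(scope="session")
def small_cohort():
    """A small full-pipeline cohort (16 ASD / 8 TD, 5-minute sessions)."""
    base = ds.DyadSimConfig(seed=0, session_duration_s=300.0)
    return ds.simulate_cohort(16, 8, seed=123, base=base)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_track(values, valid=None, shift=0.01, t0=None):
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.isfinite(values)
    if t0 is None:
        t0 = shift / 2
    return ds.FrameTrack(shift, t0, values, valid)
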