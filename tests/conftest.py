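import numpy as np
import pytest

from foragerl import envsim, synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_schedule():
    return envsim.BlockSchedule(((1, 20), (2, 20)))


@pytest.fixture(scope="session")
def stf_session(short_schedule):
    """One short synthetic STF session shared across behavioral tests."""
    cfg = synth.SynthConfig(seed=21, schedule=short_schedule)
    trace, events, truth = synth.synth_behavior_session(cfg)
    return cfg, trace, events, truth


@pytest.fixture(scope="session")
def spe_session(short_schedule):
    """Sparse-background session with injected SPEs, shared across tests."""
    cfg = synth.spe_regime(seed=8, schedule=short_schedule)
    trace, events, truth = synth.synth_behavior_session(cfg)
    roi, truth = synth.synth_neural_session(trace, truth, cfg)
    return cfg, trace, roi, truth
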