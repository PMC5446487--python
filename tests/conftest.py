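"""Shared fixtures: small simulated sessions and reduced analysis settings.

Heavy cohort-level objects are session-scoped so the expensive simulations
run once; tests must not mutate them.
"""

import numpy as np
import pytest

from sst_osc.behavior_sim import RaceConfig, TaskConfig, simulate_cohort, simulate_responder, generate_sequence
from sst_osc.observer import ObserverParams
from sst_osc.timefreq import TFConfig

#: generative observer parameters used throughout (group-level best fits)
GEN_PARAMS = dict(alpha=0.78, pm=0.14, sc=10.0)


@pytest.fixture(scope="session")
def gen_params():
    return ObserverParams(**GEN_PARAMS)


@pytest.fixture(scope="session")
def small_trials(gen_params):
    """One subject, 400 trials, default task and race settings."""
    cfg = TaskConfig(seed=11)
    return simulate_responder(generate_sequence(cfg), RaceConfig(), gen_params, cfg)


@pytest.fixture(scope="session")
def small_cohort(gen_params):
    """Six-subject cohort for group-level machinery (kept small for speed)."""
    return simulate_cohort(6, TaskConfig(seed=21), RaceConfig(), gen_params, seed=21)


@pytest.fixture(scope="session")
def fast_tf_config():
    """Reduced time-frequency grid: 20 log bins 2-30 Hz, 20 ms time steps."""
    return TFConfig(freqs_hz=np.geomspace(2.0, 30.0, 20), decimate=5)
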