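import numpy as np
import pandas as pd
import pytest

from impulsekit import synthetic as syn
from impulsekit.validation import event_grid_session


@pytest.fixture(scope="session")
def quiet_agent():
    """Agent that never pokes during the precue and always answers Go cues."""
    return syn.AgentSpec(animal_id="quiet", trait_theta=0.5,
                         precue_poke_rate_fn=lambda th: 0.0,
                         fa_prob_fn=lambda th: 0.0, go_hit_prob=1.0)


@pytest.fixture(scope="session")
def quiet_session(quiet_agent):
    return syn.simulate_session(quiet_agent, seed=11)


@pytest.fixture(scope="session")
def grid_session():
    """Session with 60 irregularly spaced precue-poke events and no noise."""
    return event_grid_session(n_events=60, seed=101)


def make_session(trials: pd.DataFrame, events: pd.DataFrame,
                 duration_s: float, motion=None,
                 motion_fs_hz: float = 10.0) -> syn.SessionLog:
    """Hand-assembled SessionLog for enumeration tests."""
    if motion is None:
        motion = pd.DataFrame({"time_s": [0.0], "motion": [50.0]})
    return syn.SessionLog(animal_id="manual", trials=trials, events=events,
                          motion=motion, duration_s=duration_s,
                          motion_fs_hz=motion_fs_hz)
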