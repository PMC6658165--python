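import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import varisk as vk
from varisk.task import EVENT_NAMES

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lg_session():
    """Value/risk agent session used across analysis tests."""
    rng = np.random.default_rng(42)
    return vk.simulate_session(vk.TaskConfig(), vk.agents.LogisticAgent(),
                               rng, n_trials=600)


@pytest.fixture(scope="session")
def fitted(lg_session):
    """Fitted history weights, decision variables and regressor frame."""
    obj_w = vk.HistoryWeightModel(lg_session, domain="object").fit()
    act_w = vk.HistoryWeightModel(lg_session, domain="action").fit()
    dv = vk.compute_decision_variables(lg_session, obj_w, act_w)
    frame = vk.variable_frame(lg_session, dv)
    return {"session": lg_session, "obj_w": obj_w, "act_w": act_w,
            "dv": dv, "frame": frame}


def make_toy_session(choices, rewards, pos_A=None, base_p=(0.3, 0.3)):
    """Hand-built session from explicit choice ('A'/'B') and reward (0/1)
    sequences; schedule columns are filled with consistent placeholder values."""
    T = len(choices)
    if pos_A is None:
        pos_A = ["L", "R"] * (T // 2 + 1)
    pos_A = list(pos_A)[:T]
    actions = [("L" if p == "L" else "R") if c == "A" else
               ("R" if p == "L" else "L") for c, p in zip(choices, pos_A)]
    rows = {
        "trial": np.arange(1, T + 1),
        "block_id": np.zeros(T, dtype=int),
        "base_p_A": np.full(T, base_p[0]),
        "base_p_B": np.full(T, base_p[1]),
        "n_unchosen_A": np.zeros(T, dtype=int),
        "n_unchosen_B": np.zeros(T, dtype=int),
        "inst_p_A": np.full(T, base_p[0]),
        "inst_p_B": np.full(T, base_p[1]),
        "baited_A": np.array(rewards, dtype=int),
        "baited_B": np.array(rewards, dtype=int),
        "pos_A": pos_A,
        "choice": list(choices),
        "action": actions,
        "reward": np.array(rewards, dtype=int),
    }
    events = {"fix_on": 500.0, "alert_on": 2000.0, "alert_off": 2800.0,
              "cue_on": 4500.0, "saccade": 5000.0, "fix_off": 5000.0,
              "cue_off": 6500.0, "outcome": 7500.0, "trial_end": 8500.0}
    for e in EVENT_NAMES:
        rows[f"t_{e}"] = np.full(T, events[e])
    return vk.Session(config=vk.TaskConfig(), trials=pd.DataFrame(rows))


@pytest.fixture
def toy_session_factory():
    return make_toy_session
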