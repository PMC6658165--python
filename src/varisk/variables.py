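"""Canonical per-trial task variables shared by the spike generator and analyses.

Coding conventions: object choice 0 = A / 1 = B; cue position 0 = A on the
left / 1 = A on the right; action 0 = left / 1 = right.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .behavior import DecisionVariables
from .task import Session

__all__ = ["variable_frame", "zscore_columns"]


def variable_frame(session: Session, dv: DecisionVariables) -> pd.DataFrame:
    """One row per trial with every named task/decision variable.

    Burn-in rows carry NaN for history-derived quantities.
    """
    d = dv.df
    out = pd.DataFrame({
        "choice": session.choice01().astype(float),
        "cue_position": session.cue_position01().astype(float),
        "action": session.action01().astype(float),
        "true_prob_A": d["true_p_A"],
        "true_prob_B": d["true_p_B"],
        "true_risk_A": d["true_risk_A"],
        "true_risk_B": d["true_risk_B"],
        "object_value_A": d["OVrc_A"],
        "object_value_B": d["OVrc_B"],
        "object_risk_A": d["var_A"],
        "object_risk_B": d["var_B"],
        "action_value_L": d["AV_L"],
        "action_value_R": d["AV_R"],
        "action_risk_L": d["avar_L"],
        "action_risk_R": d["avar_R"],
        "last_reward": d["last_reward"],
        "last_choice": d["last_choice"],
        "last_rxc": d["last_rxc"],
        "last_reward2": d["last_reward2"],
        "last_choice2": d["last_choice2"],
        "last_rxc2": d["last_rxc2"],
    })
    if "U_A" in d.columns:
        out["utility_A"] = d["U_A"]
        out["utility_B"] = d["U_B"]
    return out


def zscore_columns(frame: pd.DataFrame, valid: np.ndarray) -> pd.DataFrame:
    """Z-score each column over valid trials; invalid rows and zero-variance
    columns are set to 0 so they contribute nothing to synthetic rates."""
    out = {}
    for c in frame.columns:
        v = frame[c].to_numpy(dtype=float)
        vv = v[valid]
        vv = vv[np.isfinite(vv)]
        sd = np.std(vv)
        if sd == 0 or not np.isfinite(sd):
            out[c] = np.zeros(len(v))
        else:
            z = (v - np.mean(vv)) / sd
            z[~np.isfinite(z)] = 0.0
            z[~valid] = 0.0
            out[c] = z
    return pd.DataFrame(out)
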