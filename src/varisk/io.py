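"""CSV/JSON persistence with strict, line-numbered schema validation."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import HistoryWeightResults
from .neurons import EpochCounts, NeuronSpec
from .task import EVENT_NAMES, Session, TaskConfig

__all__ = [
    "SchemaError",
    "write_session", "read_session",
    "write_counts", "read_counts",
    "write_spike_times", "read_spike_times",
    "write_weights", "read_weights",
    "write_population", "read_population",
]

SESSION_COLUMNS = [
    "trial", "block_id", "base_p_A", "base_p_B", "n_unchosen_A",
    "n_unchosen_B", "inst_p_A", "inst_p_B", "baited_A", "baited_B",
    "pos_A", "choice", "action", "reward",
] + [f"t_{e}" for e in EVENT_NAMES]


class SchemaError(ValueError):
    """File content violates the expected schema (column and row named)."""


def _check(cond: bool, msg: str):
    if not cond:
        raise SchemaError(msg)


def write_session(session: Session, path, config_path=None):
    session.trials.to_csv(path, index=False, columns=SESSION_COLUMNS)
    if config_path is not None:
        Path(config_path).write_text(json.dumps(session.config.to_dict(),
                                                indent=1))


def read_session(path, config: TaskConfig | None = None,
                 config_path=None) -> Session:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    _check(not missing, f"session file missing columns: {missing}")
    for col in ("baited_A", "baited_B", "reward"):
        bad = ~df[col].isin([0, 1])
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SchemaError(f"malformed boolean in column '{col}', row {row}")
    for col, allowed in (("choice", {"A", "B"}), ("pos_A", {"L", "R"}),
                         ("action", {"L", "R"})):
        bad = ~df[col].isin(list(allowed))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SchemaError(f"invalid value in column '{col}', row {row}")
    tr = df["trial"].to_numpy()
    _check((tr == np.arange(1, len(df) + 1)).all(),
           "trial indices must be contiguous from 1")
    if config is None:
        if config_path is not None:
            config = TaskConfig.from_dict(json.loads(Path(config_path).read_text()))
        else:
            config = TaskConfig()
    return Session(config=config, trials=df)


def write_counts(counts: EpochCounts, path):
    counts.to_long().to_csv(path, index=False)


def read_counts(path) -> EpochCounts:
    df = pd.read_csv(path)
    missing = [c for c in ("neuron", "trial", "epoch", "count")
               if c not in df.columns]
    _check(not missing, f"counts file missing columns: {missing}")
    bad = (df["count"] < 0) | (df["count"] != df["count"].astype(int))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise SchemaError(f"invalid value in column 'count', row {row}")
    return EpochCounts.from_long(df)


def write_spike_times(spikes: pd.DataFrame, path):
    spikes.to_csv(path, index=False)


def read_spike_times(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("neuron", "trial", "t_ms") if c not in df.columns]
    _check(not missing, f"spike-time file missing columns: {missing}")
    return df


def write_weights(weights: HistoryWeightResults, path):
    Path(path).write_text(json.dumps(weights.to_dict(), indent=1))


def read_weights(path) -> HistoryWeightResults:
    d = json.loads(Path(path).read_text())
    return HistoryWeightResults(
        reward_weights=np.asarray(d["reward_weights"]),
        choice_weights=np.asarray(d["choice_weights"]),
        bias=d["bias"],
        reward_weights_se=np.asarray(d["reward_weights_se"]),
        choice_weights_se=np.asarray(d["choice_weights_se"]),
        bias_se=d["bias_se"], pvalues=pd.Series(dtype=float),
        llf=d["llf"], nobs=d["nobs"], domain=d["domain"], N=d["N"],
        converged=d["converged"], separation=d["separation"])


def write_population(specs: list[NeuronSpec], path):
    Path(path).write_text(json.dumps([s.to_dict() for s in specs], indent=1))


def read_population(path) -> list[NeuronSpec]:
    return [NeuronSpec.from_dict(d)
            for d in json.loads(Path(path).read_text())]
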