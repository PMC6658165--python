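"""Synthetic spiking populations with known tuning to task variables.

Each neuron's per-epoch firing rate is a linear function of z-scored task
variables::

    rate(trial, epoch) = baseline * drift(trial)
                       + sum_v gain[v] * z_v(trial)   [v active in epoch]

floored at zero, with Poisson spike counts over the 500-ms epoch.  Gains are
expressed in impulses/s per z-unit so tuning strengths are comparable across
variables (mirroring standardized regression coefficients).  Optional slow
drift is an AR(1) process on the log baseline.  For time-resolved analyses,
spike times are generated from a piecewise-constant rate across the whole
trial, with tuning contributions switched on inside epoch windows or inside
explicit time windows (e.g. a designed history -> risk -> choice transition
sequence with staggered onsets).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import DecisionVariables
from .task import EPOCHS, EPOCH_NAMES, Session
from .variables import variable_frame, zscore_columns

__all__ = [
    "NeuronSpec",
    "EpochCounts",
    "make_population",
    "simulate_counts",
    "simulate_spike_times",
]

EPOCH_DURATION_S = 0.5


@dataclass
class NeuronSpec:
    """Ground-truth tuning specification for one synthetic neuron.

    ``gain_map`` maps variable name -> gain (impulses/s per z-unit), active in
    the epochs listed in ``epoch_profile`` (default: all 11 epochs).
    ``time_windows`` lists (variable, gain, t_on_ms, t_off_ms) tuples relative
    to ``align_event`` for spike-time simulation; when present they replace
    the epoch-profile tuning in the spike-time pathway.
    """

    neuron_id: str
    baseline: float = 10.0
    gain_map: dict = field(default_factory=dict)
    epoch_profile: dict = field(default_factory=dict)
    time_windows: list = field(default_factory=list)
    align_event: str = "fix_on"
    drift_rho: float = 0.0
    drift_sd: float = 0.0

    def __post_init__(self):
        if self.baseline <= 0:
            raise ValueError("baseline rate must be positive")
        for var, eps in self.epoch_profile.items():
            for e in eps:
                if e not in EPOCH_NAMES:
                    raise ValueError(f"unknown epoch {e!r} for {var!r}")

    def active_epochs(self, var: str) -> tuple:
        return tuple(self.epoch_profile.get(var, EPOCH_NAMES))

    def to_dict(self) -> dict:
        return {
            "neuron_id": self.neuron_id, "baseline": self.baseline,
            "gain_map": self.gain_map,
            "epoch_profile": {k: list(v) for k, v in self.epoch_profile.items()},
            "time_windows": [list(w) for w in self.time_windows],
            "align_event": self.align_event,
            "drift_rho": self.drift_rho, "drift_sd": self.drift_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronSpec":
        d = dict(d)
        d["time_windows"] = [tuple(w) for w in d.get("time_windows", [])]
        return cls(**d)


def make_population(classes: list[dict], rng: np.random.Generator,
                    baseline_range: tuple[float, float] = (5.0, 20.0),
                    random_sign: bool = True) -> list[NeuronSpec]:
    """Build a reproducible population spec from tuning-class descriptions.

    Each class dict: ``{"n": int, "variables": [...], "gain": float,
    "epochs": [...] (optional), "transition": [(var, gain, t_on, t_off), ...]
    (optional), "drift": (rho, sd) (optional)}``.  Variables get a random
    +/- 1 sign per neuron when ``random_sign`` (risk can be coded with
    positive or negative slopes).  Untuned classes use ``"variables": []``.
    """
    specs = []
    idx = 0
    for cls in classes:
        for _ in range(int(cls["n"])):
            gain_map = {}
            profile = {}
            for var in cls.get("variables", []):
                sign = rng.choice([-1.0, 1.0]) if random_sign else 1.0
                gain_map[var] = sign * float(cls.get("gain", 6.0))
                if cls.get("epochs"):
                    profile[var] = tuple(cls["epochs"])
            windows = [tuple(w) for w in cls.get("transition", [])]
            rho, sd = cls.get("drift", (0.0, 0.0))
            specs.append(NeuronSpec(
                neuron_id=f"n{idx:04d}",
                baseline=float(rng.uniform(*baseline_range)),
                gain_map=gain_map, epoch_profile=profile,
                time_windows=windows, drift_rho=float(rho), drift_sd=float(sd)))
            idx += 1
    return specs


@dataclass
class EpochCounts:
    """Spike counts per neuron x trial x epoch (11 fixed 500-ms epochs)."""

    counts: np.ndarray  # (n_neurons, n_trials, 11) integer counts
    neuron_ids: list[str]
    epoch_names: tuple = EPOCH_NAMES
    duration_s: float = EPOCH_DURATION_S

    def __post_init__(self):
        if self.counts.ndim != 3 or self.counts.shape[2] != len(self.epoch_names):
            raise ValueError("counts must be (neurons, trials, epochs)")
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be non-negative")

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]

    @property
    def n_trials(self) -> int:
        return self.counts.shape[1]

    def rates(self) -> np.ndarray:
        """Impulse rates (impulses/s)."""
        return self.counts / self.duration_s

    def epoch_index(self, name: str) -> int:
        return self.epoch_names.index(name)

    def to_long(self) -> pd.DataFrame:
        n, T, E = self.counts.shape
        return pd.DataFrame({
            "neuron": np.repeat(self.neuron_ids, T * E),
            "trial": np.tile(np.repeat(np.arange(1, T + 1), E), n),
            "epoch": np.tile(list(self.epoch_names), n * T),
            "count": self.counts.reshape(-1),
        })

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "EpochCounts":
        ids = list(pd.unique(df["neuron"]))
        trials = np.sort(pd.unique(df["trial"]))
        piv = df.pivot_table(index=["neuron", "trial"], columns="epoch",
                             values="count", sort=False)
        piv = piv.reindex(columns=list(EPOCH_NAMES))
        arr = np.empty((len(ids), len(trials), len(EPOCH_NAMES)), dtype=int)
        for i, nid in enumerate(ids):
            arr[i] = piv.loc[nid].reindex(trials).to_numpy()
        return cls(counts=arr, neuron_ids=ids)


def _drift(spec: NeuronSpec, T: int, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative AR(1) drift on the baseline, exp(d_t)."""
    if spec.drift_sd == 0:
        return np.ones(T)
    d = np.zeros(T)
    innov = rng.normal(0.0, spec.drift_sd, size=T)
    for i in range(1, T):
        d[i] = spec.drift_rho * d[i - 1] + innov[i]
    return np.exp(d)


def _zframe(session: Session, dv: DecisionVariables) -> pd.DataFrame:
    frame = variable_frame(session, dv)
    return zscore_columns(frame, dv.valid)


def simulate_counts(session: Session, dv: DecisionVariables,
                    specs: list[NeuronSpec], rng: np.random.Generator,
                    zframe: pd.DataFrame | None = None) -> EpochCounts:
    """Poisson epoch counts for a population given the session's variables.

    Returns an :class:`EpochCounts`; a warning counter of rate-floored
    (rate < 0 before clipping) neuron-trial-epochs is attached as
    ``.n_floored``.
    """
    if zframe is None:
        zframe = _zframe(session, dv)
    T = session.n_trials
    E = len(EPOCH_NAMES)
    counts = np.empty((len(specs), T, E), dtype=int)
    n_floored = 0
    for i, spec in enumerate(specs):
        drift = _drift(spec, T, rng)
        rate = np.tile((spec.baseline * drift)[:, None], (1, E))
        for var, gain in spec.gain_map.items():
            z = zframe[var].to_numpy()
            for e in spec.active_epochs(var):
                rate[:, EPOCH_NAMES.index(e)] += gain * z
        n_floored += int((rate < 0).sum())
        rate = np.clip(rate, 0.0, None)
        counts[i] = rng.poisson(rate * EPOCH_DURATION_S)
    out = EpochCounts(counts=counts, neuron_ids=[s.neuron_id for s in specs])
    out.n_floored = n_floored
    return out


def _epoch_windows(trial_row: pd.Series) -> list[tuple[str, float, float]]:
    """Absolute (name, start, end) ms windows of the 11 epochs for one trial."""
    wins = []
    for name, event, off, dur in EPOCHS:
        t0 = float(trial_row[f"t_{event}"]) + off
        wins.append((name, t0, t0 + dur))
    return wins


def simulate_spike_times(session: Session, dv: DecisionVariables,
                         specs: list[NeuronSpec], rng: np.random.Generator,
                         zframe: pd.DataFrame | None = None) -> pd.DataFrame:
    """Spike times from a piecewise-constant rate across each trial.

    Baseline (with drift) applies everywhere from 0 to trial end.  If a
    neuron has ``time_windows`` those define its tuning windows (relative to
    ``align_event``); otherwise the epoch-profile tuning is laid onto the
    epoch windows.  Returns a long DataFrame ``neuron, trial, t_ms``.
    """
    if zframe is None:
        zframe = _zframe(session, dv)
    trials = session.trials
    T = session.n_trials
    rows_n, rows_t, rows_ms = [], [], []
    for spec in specs:
        drift = _drift(spec, T, rng)
        for ti in range(T):
            row = trials.iloc[ti]
            t_end = float(row["t_trial_end"])
            # collect (start, end, added rate) contributions
            contribs = []
            if spec.time_windows:
                t0_evt = float(row[f"t_{spec.align_event}"])
                for var, gain, on, off in spec.time_windows:
                    z = zframe[var].iloc[ti]
                    contribs.append((t0_evt + on, t0_evt + off, gain * z))
            else:
                wins = dict((n, (a, b)) for n, a, b in _epoch_windows(row))
                for var, gain in spec.gain_map.items():
                    z = zframe[var].iloc[ti]
                    for e in spec.active_epochs(var):
                        a, b = wins[e]
                        contribs.append((a, b, gain * z))
            edges = {0.0, t_end}
            for a, b, _ in contribs:
                edges.add(min(max(a, 0.0), t_end))
                edges.add(min(max(b, 0.0), t_end))
            edges = sorted(edges)
            base = spec.baseline * drift[ti]
            spikes = []
            for a, b in zip(edges[:-1], edges[1:]):
                if b <= a:
                    continue
                mid = 0.5 * (a + b)
                rate = base + sum(g for s, e, g in contribs if s <= mid < e)
                rate = max(rate, 0.0)
                k = rng.poisson(rate * (b - a) / 1000.0)
                if k:
                    spikes.append(np.sort(rng.uniform(a, b, size=k)))
            if spikes:
                st = np.concatenate(spikes)
                rows_n.extend([spec.neuron_id] * len(st))
                rows_t.extend([ti + 1] * len(st))
                rows_ms.extend(np.round(st, 3))
    return pd.DataFrame({"neuron": rows_n, "trial": rows_t, "t_ms": rows_ms})
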