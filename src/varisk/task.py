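"""Baited two-object matching task: schedule, baiting state machine, session simulation.

The task presents two visual objects (A, B) on randomly alternating sides of
fixation.  Reward is assigned to each object independently and stochastically
with a block-wise *base probability* ``P0``; once assigned ("baited") the
reward persists until the object is chosen.  Consequently the instantaneous
reward probability of an object grows with the number ``n`` of consecutive
trials it was left unchosen::

    P = 1 - (1 - P0) ** (n + 1)

which is the classic concurrent variable-interval contingency that produces
matching behavior.  With a fixed juice magnitude ``m`` the objective
(variance) risk of choosing an object is the Bernoulli outcome variance
``p * (1 - p) * m**2``, an inverted-U function of ``p``.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EPOCHS",
    "EPOCH_NAMES",
    "EVENT_NAMES",
    "TaskConfig",
    "Session",
    "scheduled_probability",
    "objective_risk",
    "simulate_session",
]

#: Canonical 11 task epochs: (name, alignment event, offset ms, duration ms).
#: Pre-fix is the control period (no stimuli on screen yet).
EPOCHS: tuple[tuple[str, str, float, float], ...] = (
    ("Pre-fix", "fix_on", -500.0, 500.0),
    ("Fix", "fix_on", 0.0, 500.0),
    ("Fix2", "fix_on", 500.0, 500.0),
    ("Pre-cue", "cue_on", -500.0, 500.0),
    ("Cue", "cue_on", 0.0, 500.0),
    ("Post-fix", "fix_off", 0.0, 500.0),
    ("Pre-cue off", "cue_off", -500.0, 500.0),
    ("Post-cue off", "cue_off", 0.0, 500.0),
    ("Pre-outc", "outcome", -500.0, 500.0),
    ("Outc", "outcome", 0.0, 500.0),
    ("Outc2", "outcome", 500.0, 500.0),
)

EPOCH_NAMES: tuple[str, ...] = tuple(e[0] for e in EPOCHS)

EVENT_NAMES: tuple[str, ...] = (
    "fix_on",
    "alert_on",
    "alert_off",
    "cue_on",
    "saccade",
    "fix_off",
    "cue_off",
    "outcome",
    "trial_end",
)


def scheduled_probability(P0, n):
    """Instantaneous reward probability after ``n`` consecutive unchosen trials.

    Parameters
    ----------
    P0 : float or array
        Base (programmed) per-trial assignment probability, in (0, 1].
    n : int or array
        Number of consecutive trials the object was unchosen (>= 0).

    Returns
    -------
    float or ndarray
        ``1 - (1 - P0) ** (n + 1)``, clipped to [0, 1].
    """
    P0 = np.asarray(P0, dtype=float)
    n = np.asarray(n)
    if np.any((P0 <= 0) | (P0 > 1)):
        raise ValueError("base probability must lie in (0, 1]")
    if np.any(n < 0):
        raise ValueError("number of unchosen trials must be non-negative")
    out = 1.0 - (1.0 - P0) ** (np.asarray(n, dtype=float) + 1.0)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def objective_risk(p, m=0.7):
    """Objective variance risk of a two-outcome reward lottery.

    The reward distribution is Bernoulli over outcomes {0, m}; its variance
    is ``p * (1 - p) * m**2`` (ml^2 for juice rewards).  The function is
    symmetric about p = 0.5 where it attains its maximum ``m**2 / 4``.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probability must lie in [0, 1]")
    if np.any(np.asarray(m, dtype=float) <= 0):
        raise ValueError("reward magnitude must be positive")
    out = p * (1.0 - p) * float(m) ** 2
    return float(out) if out.ndim == 0 else out


def _default_pairs(prob_sum: float, lo: float = 0.05, hi: float = 0.55,
                   step: float = 0.05) -> list[tuple[float, float]]:
    """Admissible (P0_A, P0_B) grid with constant sum and both members in [lo, hi]."""
    pairs = []
    k = int(round((hi - lo) / step)) + 1
    for i in range(k):
        a = round(lo + i * step, 10)
        b = round(prob_sum - a, 10)
        if lo - 1e-9 <= b <= hi + 1e-9:
            pairs.append((a, round(b, 10)))
    if not pairs:
        raise ValueError(f"no admissible base-probability pairs for sum {prob_sum}")
    return pairs


@dataclass
class TaskConfig:
    """Parameters of the baited matching task.

    ``base_prob_pairs`` defaults to the 0.05-step grid of pairs summing to
    ``prob_sum`` with each member in [0.05, 0.55].  Blocks draw a pair at
    random (never repeating the previous pair) and a uniform integer length
    from ``block_length_range``.
    """

    prob_sum: float = 0.6
    base_prob_pairs: list[tuple[float, float]] | None = None
    block_length_range: tuple[int, int] = (50, 150)
    n_blocks: int = 8
    reward_magnitude: float = 0.7
    epoch_table: tuple = EPOCHS

    def __post_init__(self):
        if self.base_prob_pairs is None:
            self.base_prob_pairs = _default_pairs(self.prob_sum)
        for a, b in self.base_prob_pairs:
            if not (0.05 - 1e-9 <= a <= 0.55 + 1e-9 and 0.05 - 1e-9 <= b <= 0.55 + 1e-9):
                raise ValueError(f"base probability pair ({a}, {b}) outside [0.05, 0.55]")
            if abs(a + b - self.prob_sum) > 1e-9:
                raise ValueError(f"pair ({a}, {b}) does not sum to {self.prob_sum}")
        lo, hi = self.block_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid block length range")
        if len(self.epoch_table) != 11 or any(e[3] != 500.0 for e in self.epoch_table):
            raise ValueError("epoch table must contain 11 epochs of 500 ms")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["epoch_table"] = [list(e) for e in self.epoch_table]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        d = dict(d)
        if "epoch_table" in d:
            d["epoch_table"] = tuple(tuple(e) for e in d["epoch_table"])
        if "base_prob_pairs" in d and d["base_prob_pairs"] is not None:
            d["base_prob_pairs"] = [tuple(p) for p in d["base_prob_pairs"]]
        if "block_length_range" in d:
            d["block_length_range"] = tuple(d["block_length_range"])
        return cls(**d)


@dataclass
class Session:
    """One simulated behavioral session: a trial table plus its task config.

    ``trials`` has one row per trial with columns
    ``trial, block_id, base_p_A, base_p_B, n_unchosen_A, n_unchosen_B,
    inst_p_A, inst_p_B, baited_A, baited_B, pos_A, choice, action, reward``
    and one ``t_<event>`` column (ms, trial-relative) per trial event.
    """

    config: TaskConfig
    trials: pd.DataFrame
    agent_id: str = ""

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def choice01(self) -> np.ndarray:
        """Object choice coded 0 for A, 1 for B."""
        return (self.trials["choice"].to_numpy() == "B").astype(int)

    def action01(self) -> np.ndarray:
        """Action coded 0 for left, 1 for right."""
        return (self.trials["action"].to_numpy() == "R").astype(int)

    def cue_position01(self) -> np.ndarray:
        """Cue position coded 0 for object A on the left, 1 for A on the right."""
        return (self.trials["pos_A"].to_numpy() == "R").astype(int)

    def event_times(self) -> pd.DataFrame:
        return self.trials[[f"t_{e}" for e in EVENT_NAMES]]


def _balanced_positions(n: int, rng: np.random.Generator) -> np.ndarray:
    """Pseudorandomized L/R sequence for object A, balanced within blocks of 4."""
    reps = (n + 3) // 4
    out = np.empty((reps, 4), dtype="<U1")
    for i in range(reps):
        block = np.array(["L", "L", "R", "R"])
        rng.shuffle(block)
        out[i] = block
    return out.ravel()[:n]


def _draw_events(rng: np.random.Generator) -> dict[str, float]:
    """Trial event times (ms, relative to trial start) with task-stated jitters."""
    t = {}
    t["fix_on"] = 500.0
    t["alert_on"] = t["fix_on"] + rng.uniform(1000.0, 2000.0)
    t["alert_off"] = t["alert_on"] + rng.uniform(700.0, 1000.0)
    t["cue_on"] = t["alert_off"] + rng.uniform(1400.0, 2000.0)
    t["saccade"] = t["cue_on"] + rng.uniform(250.0, 750.0)
    t["fix_off"] = t["saccade"]
    t["cue_off"] = t["saccade"] + rng.uniform(1000.0, 2000.0)
    t["outcome"] = t["cue_off"] + rng.uniform(600.0, 1300.0)
    t["trial_end"] = t["outcome"] + 1000.0
    return t


def simulate_session(config: TaskConfig, agent, rng: np.random.Generator,
                     n_trials: int | None = None, agent_id: str = "") -> Session:
    """Simulate a session of the baited matching task.

    Each trial proceeds as: (1) every unbaited object becomes baited with its
    current base probability and the bait persists; (2) the agent chooses an
    object given the cue position; (3) choosing a baited object delivers the
    reward and clears the bait; the chosen object's unchosen-counter resets to
    0 while the other's increments.  The recorded ``inst_p`` is the marginal
    availability probability 1-(1-P0)^(n+1) implied by the counter at choice
    time.

    Parameters
    ----------
    config : TaskConfig
    agent : object
        Must implement ``choose(pos_A, rng) -> 'A' | 'B'`` and
        ``update(choice, reward, pos_A)``; ``reset()`` is called first if
        present.
    rng : numpy Generator
        Sole source of randomness; identical seed + config + agent give an
        identical session.
    n_trials : int, optional
        Truncate/extend the session to exactly this many trials (blocks are
        drawn until the count is reached, ignoring ``config.n_blocks``).
    """
    if hasattr(agent, "reset"):
        agent.reset()

    rows = []
    baited = {"A": False, "B": False}
    n_unchosen = {"A": 0, "B": 0}
    prev_pair = None
    trial = 0
    block_id = 0
    target = n_trials if n_trials is not None else None

    pos_seq: list[str] = []

    def blocks():
        for b in itertools.count():
            yield b

    for block_id in blocks():
        if target is None and block_id >= config.n_blocks:
            break
        if target is not None and trial >= target:
            break
        # draw a base-probability pair, avoiding an immediate repeat
        pairs = config.base_prob_pairs
        idx = int(rng.integers(len(pairs)))
        if len(pairs) > 1:
            while pairs[idx] == prev_pair:
                idx = int(rng.integers(len(pairs)))
        pair = pairs[idx]
        prev_pair = pair
        base_p = {"A": pair[0], "B": pair[1]}
        block_len = int(rng.integers(config.block_length_range[0],
                                     config.block_length_range[1] + 1))

        for _ in range(block_len):
            if target is not None and trial >= target:
                break
            if not pos_seq:
                pos_seq = list(_balanced_positions(4, rng))
            pos_A = pos_seq.pop(0)

            # 1) baiting: independent assignment, persists until chosen
            for obj in ("A", "B"):
                if not baited[obj]:
                    baited[obj] = bool(rng.random() < base_p[obj])

            inst_p = {obj: scheduled_probability(base_p[obj], n_unchosen[obj])
                      for obj in ("A", "B")}
            baited_now = dict(baited)

            # 2) choice
            choice = agent.choose(pos_A, rng)
            if choice not in ("A", "B"):
                raise ValueError(f"agent returned invalid choice {choice!r}")
            action = ("L" if pos_A == "L" else "R") if choice == "A" else \
                     ("R" if pos_A == "L" else "L")

            # 3) outcome
            reward = baited[choice]
            baited[choice] = False

            events = _draw_events(rng)
            row = {
                "trial": trial + 1,
                "block_id": block_id,
                "base_p_A": base_p["A"],
                "base_p_B": base_p["B"],
                "n_unchosen_A": n_unchosen["A"],
                "n_unchosen_B": n_unchosen["B"],
                "inst_p_A": inst_p["A"],
                "inst_p_B": inst_p["B"],
                "baited_A": int(baited_now["A"]),
                "baited_B": int(baited_now["B"]),
                "pos_A": pos_A,
                "choice": choice,
                "action": action,
                "reward": int(reward),
            }
            row.update({f"t_{k}": round(v, 3) for k, v in events.items()})
            rows.append(row)

            for obj in ("A", "B"):
                n_unchosen[obj] = 0 if obj == choice else n_unchosen[obj] + 1
            agent.update(choice, bool(reward), pos_A)
            trial += 1
        if target is not None and trial >= target:
            break

    trials = pd.DataFrame(rows)
    return Session(config=config, trials=trials,
                   agent_id=agent_id or type(agent).__name__)
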