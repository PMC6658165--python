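"""Generative choice agents for the baited matching task.

Agents implement ``choose(pos_A, rng)`` / ``update(choice, reward, pos_A)``.
``HistoryAgent`` generates choices directly from the history-weighted logistic
policy (the same form the history-weight regression estimates), while
``LogisticAgent`` computes subjective value and risk online from its own
weighting function and chooses by a value/risk trade-off in the left/right
frame — a risk-seeking agent when its risk weight is positive.
"""

from __future__ import annotations

from collections import deque

import numpy as np

__all__ = [
    "RandomAgent",
    "FixedAgent",
    "AlternatingAgent",
    "HistoryAgent",
    "LogisticAgent",
    "RLAgent",
    "default_reward_weights",
    "default_choice_weights",
]

N_HISTORY = 10


def default_reward_weights(N: int = N_HISTORY) -> np.ndarray:
    """Exponentially decaying reward-history weights, 1.5 * exp(-j/2)."""
    j = np.arange(1, N + 1)
    return 1.5 * np.exp(-j / 2.0)


def default_choice_weights(N: int = N_HISTORY) -> np.ndarray:
    """Exponentially decaying choice-history weights, 0.8 * exp(-j/2)."""
    j = np.arange(1, N + 1)
    return 0.8 * np.exp(-j / 2.0)


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


class RandomAgent:
    """Chooses A or B with fixed probability, ignoring history."""

    def __init__(self, p_A: float = 0.5):
        self.p_A = p_A

    def reset(self):
        pass

    def choose(self, pos_A, rng):
        return "A" if rng.random() < self.p_A else "B"

    def update(self, choice, reward, pos_A):
        pass


class FixedAgent:
    """Always chooses the same object."""

    def __init__(self, obj: str = "A"):
        self.obj = obj

    def reset(self):
        pass

    def choose(self, pos_A, rng):
        return self.obj

    def update(self, choice, reward, pos_A):
        pass


class AlternatingAgent:
    """Strictly alternates A, B, A, B, ..."""

    def reset(self):
        self._next = "A"

    def choose(self, pos_A, rng):
        return self._next

    def update(self, choice, reward, pos_A):
        self._next = "B" if choice == "A" else "A"


class _HistoryState:
    """Rolling N-trial record of object-referenced reward/choice indicators."""

    def __init__(self, N: int = N_HISTORY):
        self.N = N
        # index 0 = most recent past trial (j = 1)
        self.RA = deque(maxlen=N)
        self.RB = deque(maxlen=N)
        self.CA = deque(maxlen=N)
        self.CB = deque(maxlen=N)

    def push(self, choice: str, reward: bool):
        a = choice == "A"
        self.RA.appendleft(int(a and reward))
        self.RB.appendleft(int((not a) and reward))
        self.CA.appendleft(int(a))
        self.CB.appendleft(int(not a))

    @property
    def full(self) -> bool:
        return len(self.CA) == self.N


class HistoryAgent:
    """Chooses objects from the history-weighted logistic policy.

    log(pA/pB) = sum_j w_r[j-1] * (RA(i-j) - RB(i-j))
               + sum_j w_c[j-1] * (CA(i-j) - CB(i-j)) + bias.
    Before N past trials exist the agent chooses at random.
    """

    def __init__(self, reward_weights=None, choice_weights=None, bias: float = 0.0,
                 N: int = N_HISTORY):
        self.w_r = np.asarray(reward_weights if reward_weights is not None
                              else default_reward_weights(N), dtype=float)
        self.w_c = np.asarray(choice_weights if choice_weights is not None
                              else default_choice_weights(N), dtype=float)
        self.bias = bias
        self.N = N

    def reset(self):
        self._h = _HistoryState(self.N)

    def choose(self, pos_A, rng):
        if not self._h.full:
            return "A" if rng.random() < 0.5 else "B"
        dr = np.array(self._h.RA) - np.array(self._h.RB)
        dc = np.array(self._h.CA) - np.array(self._h.CB)
        logit = float(self.w_r @ dr + self.w_c @ dc + self.bias)
        return "A" if rng.random() < _sigmoid(logit) else "B"

    def update(self, choice, reward, pos_A):
        self._h.push(choice, reward)


class LogisticAgent:
    """Value/risk trade-off agent in the left/right frame.

    On each trial the agent computes, from its own history-weighting function,
    the subjective value (weighted reward + choice history, single denominator
    N) and subjective risk (weighted squared deviation from the unweighted
    window mean, denominator N-1) of each object, maps them to screen sides
    via the cue position, and chooses left with probability
    sigmoid(beta0 + beta1*dValue + beta2*dRisk) where d* = left - right.
    beta2 > 0 makes the agent risk seeking.  During the first N (burn-in)
    trials it chooses each side with probability 0.5.
    """

    def __init__(self, beta0: float = 0.0, beta1: float = 20.0, beta2: float = 2.0,
                 reward_weights=None, choice_weights=None, N: int = N_HISTORY):
        self.beta0, self.beta1, self.beta2 = beta0, beta1, beta2
        self.w_r = np.asarray(reward_weights if reward_weights is not None
                              else default_reward_weights(N), dtype=float)
        self.w_c = np.asarray(choice_weights if choice_weights is not None
                              else default_choice_weights(N), dtype=float)
        self.N = N

    def reset(self):
        self._h = _HistoryState(self.N)

    def _value_risk(self, R, C):
        R = np.asarray(R, dtype=float)
        C = np.asarray(C, dtype=float)
        value = (self.w_r @ R + self.w_c @ C) / self.N
        mean = R.sum() / self.N
        risk = float(self.w_r @ (R - mean) ** 2) / (self.N - 1)
        return float(value), risk

    def choose(self, pos_A, rng):
        if not self._h.full:
            side = "L" if rng.random() < 0.5 else "R"
        else:
            vA, rA = self._value_risk(self._h.RA, self._h.CA)
            vB, rB = self._value_risk(self._h.RB, self._h.CB)
            if pos_A == "L":
                dv, dr = vA - vB, rA - rB
            else:
                dv, dr = vB - vA, rB - rA
            p_left = _sigmoid(self.beta0 + self.beta1 * dv + self.beta2 * dr)
            side = "L" if rng.random() < p_left else "R"
        if side == "L":
            return "A" if pos_A == "L" else "B"
        return "B" if pos_A == "L" else "A"

    def update(self, choice, reward, pos_A):
        self._h.push(choice, reward)


class RLAgent:
    """Rescorla-Wagner agent with softmax over the two object values.

    ``variant='standard'`` updates only the chosen option; ``'stack'`` in
    addition grows the unchosen option's value toward 1 at rate ``kappa``
    (availability accumulation under baiting); ``'reversal'`` updates the
    unchosen option toward the complementary outcome.
    """

    def __init__(self, alpha: float = 0.3, tau: float = 5.0, kappa: float = 0.2,
                 variant: str = "standard"):
        if variant not in ("standard", "stack", "reversal"):
            raise ValueError(f"unknown RL variant {variant!r}")
        self.alpha, self.tau, self.kappa, self.variant = alpha, tau, kappa, variant

    def reset(self):
        self.V = {"A": 0.5, "B": 0.5}

    def choose(self, pos_A, rng):
        p_A = _sigmoid(self.tau * (self.V["A"] - self.V["B"]))
        return "A" if rng.random() < p_A else "B"

    def update(self, choice, reward, pos_A):
        other = "B" if choice == "A" else "A"
        r = float(reward)
        self.V[choice] += self.alpha * (r - self.V[choice])
        if self.variant == "stack":
            self.V[other] += self.kappa * (1.0 - self.V[other])
        elif self.variant == "reversal":
            self.V[other] += self.alpha * ((1.0 - r) - self.V[other])
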