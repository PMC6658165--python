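"""History-weighted subjective decision variables.

The influence of past rewards and past choices on the current choice is
estimated with a logistic regression on reward-difference and
choice-difference regressors over the last N = 10 trials::

    log(pA/pB) = sum_j b_r[j] (RA(i-j) - RB(i-j))
               + sum_j b_c[j] (CA(i-j) - CB(i-j)) + b0

where RA(i-j) = 1 only if object A was chosen *and* rewarded on trial i-j,
and CA(i-j) = 1 if A was chosen.  The fitted reward weights then define

* subjective object value  OV_r   = sum_j b_r[j] RA(i-j) / N          (reward history)
*                          OV_rc  = (sum_j b_r[j] RA + sum_j b_c[j] CA) / N
* subjective object risk   var_A  = sum_j b_r[j] (RA(i-j) - mean)^2 / (N-1)

with ``mean`` the unweighted window mean of RA.  The same construction in the
left/right frame (reward/choice indicators referenced to saccade direction,
weights refit on action choice) yields action value and action risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .task import Session, objective_risk

__all__ = [
    "build_history_matrix",
    "HistoryWeightModel",
    "HistoryWeightResults",
    "DecisionVariables",
    "compute_decision_variables",
    "add_utility",
    "robust_logit",
]

N_HISTORY = 10


def robust_logit(y, X):
    """Maximum-likelihood logit with a ridge fallback under separation.

    Returns ``(params, bse, pvalues, llf, separation)``; on (quasi-)perfect
    separation or non-convergence the fit falls back to a lightly penalized
    binomial GLM and standard errors/p-values are reported as NaN.
    """
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", True) or \
                not np.all(np.isfinite(res.bse)):
            raise RuntimeError("non-convergence")
        return res.params, res.bse, res.pvalues, float(res.llf), False
    except Exception:
        glm = sm.GLM(y, X, family=sm.families.Binomial())
        res = glm.fit_regularized(alpha=1e-3, L1_wt=0.0)
        params = pd.Series(np.asarray(res.params), index=X.columns)
        nanser = pd.Series(np.nan, index=X.columns)
        mu = glm.predict(res.params)
        llf = float(np.sum(y * np.log(mu + 1e-12)
                           + (1 - y) * np.log(1 - mu + 1e-12)))
        return params, nanser, nanser, llf, True


def _indicators(session: Session, domain: str):
    """Per-trial reward and choice indicators for the two alternatives.

    Object domain: alternatives (A, B); action domain: alternatives (L, R).
    Reward indicator for an alternative is 1 only if it was selected *and*
    rewarded on that trial.
    """
    rew = session.trials["reward"].to_numpy().astype(float)
    if domain == "object":
        sel1 = (session.trials["choice"].to_numpy() == "A").astype(float)
    elif domain == "action":
        sel1 = (session.trials["action"].to_numpy() == "L").astype(float)
    else:
        raise ValueError(f"unknown domain {domain!r}")
    sel2 = 1.0 - sel1
    return sel1 * rew, sel2 * rew, sel1, sel2


def _lagged_sum(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """y[i] = sum_{j=1..N} weights[j-1] * x[i-j], zero-padded at the start."""
    kernel = np.concatenate(([0.0], np.asarray(weights, dtype=float)))
    return np.convolve(x, kernel)[: len(x)]


def build_history_matrix(session: Session, N: int = N_HISTORY,
                         domain: str = "object"):
    """Design matrix and response for the history-weight logistic regression.

    Returns ``(X, y, trial_idx)`` where ``X`` is a DataFrame with columns
    ``rdiff_1..rdiff_N, cdiff_1..cdiff_N, const``, ``y`` codes the choice of
    the first alternative (A, or left) as 1, and ``trial_idx`` gives the
    0-based indices of the retained (post-burn-in) trials.
    """
    T = session.n_trials
    if T <= N:
        raise ValueError(f"session has {T} trials; need more than N={N}")
    R1, R2, C1, C2 = _indicators(session, domain)
    dR, dC = R1 - R2, C1 - C2
    cols = {}
    for j in range(1, N + 1):
        lag = np.concatenate((np.full(j, np.nan), dR[: T - j]))
        cols[f"rdiff_{j}"] = lag
        lag = np.concatenate((np.full(j, np.nan), dC[: T - j]))
        cols[f"cdiff_{j}"] = lag
    X = pd.DataFrame(cols)
    X["const"] = 1.0
    keep = np.arange(N, T)
    X = X.iloc[keep].reset_index(drop=True)
    y = C1[keep]
    return X, y, keep


@dataclass
class HistoryWeightResults:
    """Fitted history weights: reward weights b_r[j], choice weights b_c[j], bias."""

    reward_weights: np.ndarray
    choice_weights: np.ndarray
    bias: float
    reward_weights_se: np.ndarray
    choice_weights_se: np.ndarray
    bias_se: float
    pvalues: pd.Series
    llf: float
    nobs: int
    domain: str
    N: int
    converged: bool = True
    separation: bool = False

    def significant(self, alpha: float = 0.005) -> pd.Series:
        """Per-coefficient significance flags (default threshold p < 0.005)."""
        return self.pvalues < alpha

    def summary(self) -> str:
        lines = [f"History-weight logistic regression ({self.domain} domain, "
                 f"N={self.N}, n={self.nobs}, llf={self.llf:.2f})"]
        lines.append(f"{'lag':>4} {'b_r':>9} {'se':>8} {'b_c':>9} {'se':>8}")
        for j in range(self.N):
            lines.append(f"{j + 1:>4} {self.reward_weights[j]:>9.4f} "
                         f"{self.reward_weights_se[j]:>8.4f} "
                         f"{self.choice_weights[j]:>9.4f} "
                         f"{self.choice_weights_se[j]:>8.4f}")
        lines.append(f"bias {self.bias:.4f} (se {self.bias_se:.4f})")
        if self.separation:
            lines.append("warning: separation detected; penalized fallback fit")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "domain": self.domain,
            "N": self.N,
            "reward_weights": self.reward_weights.tolist(),
            "choice_weights": self.choice_weights.tolist(),
            "bias": self.bias,
            "reward_weights_se": self.reward_weights_se.tolist(),
            "choice_weights_se": self.choice_weights_se.tolist(),
            "bias_se": self.bias_se,
            "llf": self.llf,
            "nobs": self.nobs,
            "converged": self.converged,
            "separation": self.separation,
        }


class HistoryWeightModel:
    """Logistic regression of current choice on reward and choice history.

    Parameters
    ----------
    session : Session
    N : int
        Number of past trials (default 10).
    domain : {'object', 'action'}
        Whether the response is object choice (A vs B) or action choice
        (left vs right), with correspondingly referenced history indicators.
    """

    def __init__(self, session: Session, N: int = N_HISTORY,
                 domain: str = "object"):
        self.session = session
        self.N = N
        self.domain = domain
        self.X, self.y, self.trial_idx = build_history_matrix(session, N, domain)

    def fit(self) -> HistoryWeightResults:
        X = self.X
        dropped = [c for c in X.columns if c != "const" and X[c].std() == 0]
        if dropped:
            import warnings
            warnings.warn(f"dropping degenerate history columns: {dropped}")
            X = X.drop(columns=dropped)
        params, bse, pvals, llf, separation = robust_logit(self.y, X)
        conv = True

        def col(prefix, j, src):
            name = f"{prefix}_{j}"
            return float(src[name]) if name in src.index else 0.0

        rw = np.array([col("rdiff", j, params) for j in range(1, self.N + 1)])
        cw = np.array([col("cdiff", j, params) for j in range(1, self.N + 1)])
        rw_se = np.array([col("rdiff", j, bse) for j in range(1, self.N + 1)])
        cw_se = np.array([col("cdiff", j, bse) for j in range(1, self.N + 1)])
        return HistoryWeightResults(
            reward_weights=rw, choice_weights=cw, bias=float(params["const"]),
            reward_weights_se=rw_se, choice_weights_se=cw_se,
            bias_se=float(bse["const"]), pvalues=pvals, llf=float(llf),
            nobs=len(self.y), domain=self.domain, N=self.N,
            converged=conv, separation=separation)


def _window_value_risk(R: np.ndarray, C: np.ndarray, w_r: np.ndarray,
                       w_c: np.ndarray, N: int, weighted_mean: bool = False):
    """Vectorized subjective value/risk of one alternative over a session.

    Returns (OV_r, OV_c, OV_rc, var) arrays; entries before trial N are NaN.
    With ``weighted_mean=True`` the deviation mean is the weight-normalized
    weighted mean instead of the plain window mean (exploratory variant).
    """
    T = len(R)
    S_wR = _lagged_sum(R, w_r)
    S_wC = _lagged_sum(C, w_c)
    S_R = _lagged_sum(R, np.ones(N))
    OV_r = S_wR / N
    OV_c = S_wC / N
    OV_rc = (S_wR + S_wC) / N
    if weighted_mean:
        mean = _lagged_sum(R, w_r) / np.sum(w_r)
    else:
        mean = S_R / N
    W = np.sum(w_r)
    # sum_j w_j (R(i-j) - mean_i)^2 = sum_j w_j R - 2 mean_i sum_j w_j R + mean_i^2 W
    # (R binary so R^2 = R)
    S_wR2 = _lagged_sum(R * R, w_r)
    var = (S_wR2 - 2.0 * mean * S_wR + mean**2 * W) / (N - 1)
    for arr in (OV_r, OV_c, OV_rc, var):
        arr[:N] = np.nan
    return OV_r, OV_c, OV_rc, var


@dataclass
class DecisionVariables:
    """Per-trial decision variables aligned to a session's trial table.

    ``df`` columns (burn-in rows NaN): subjective object values ``OVr_*``,
    ``OVc_*``, ``OVrc_*`` and risks ``var_*`` for A/B; objective ``true_p_*``
    and ``true_risk_*``; action values ``AV_L/R`` and risks ``avar_L/R``;
    last-trial history codes; left/right-mapped ``value_L/R``, ``risk_L/R``
    and their differences ``dvalue_lr``, ``drisk_lr``; utilities ``U_A/B``
    once :func:`add_utility` has been applied.
    """

    df: pd.DataFrame
    N: int
    object_weights: HistoryWeightResults | None = None
    action_weights: HistoryWeightResults | None = None

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of post-burn-in trials."""
        return ~self.df["var_A"].isna().to_numpy()


def compute_decision_variables(session: Session,
                               object_weights,
                               action_weights=None,
                               N: int = N_HISTORY,
                               weighted_mean: bool = False) -> DecisionVariables:
    """Construct all per-trial decision variables from fitted history weights.

    ``object_weights`` / ``action_weights`` may be :class:`HistoryWeightResults`
    or plain ``(reward_weights, choice_weights)`` tuples; generative weights can
    therefore be injected directly in simulations.
    """
    def unpack(w):
        if w is None:
            return None, None
        if isinstance(w, HistoryWeightResults):
            return w.reward_weights, w.choice_weights
        return np.asarray(w[0], dtype=float), np.asarray(w[1], dtype=float)

    w_r, w_c = unpack(object_weights)
    aw_r, aw_c = unpack(action_weights)

    t = session.trials
    T = session.n_trials
    out = pd.DataFrame({"trial": t["trial"].to_numpy()})

    RA, RB, CA, CB = _indicators(session, "object")
    for obj, R, C in (("A", RA, CA), ("B", RB, CB)):
        OV_r, OV_c, OV_rc, var = _window_value_risk(R, C, w_r, w_c, N, weighted_mean)
        out[f"OVr_{obj}"] = OV_r
        out[f"OVc_{obj}"] = OV_c
        out[f"OVrc_{obj}"] = OV_rc
        out[f"var_{obj}"] = var

    m = session.config.reward_magnitude
    for obj in ("A", "B"):
        out[f"true_p_{obj}"] = t[f"inst_p_{obj}"].to_numpy()
        out[f"true_risk_{obj}"] = objective_risk(t[f"inst_p_{obj}"].to_numpy(), m)

    if aw_r is not None:
        RL, RR, CL, CR = _indicators(session, "action")
        for act, R, C in (("L", RL, CL), ("R", RR, CR)):
            _, _, OV_rc, var = _window_value_risk(R, C, aw_r, aw_c, N, weighted_mean)
            out[f"AV_{act}"] = OV_rc
            out[f"avar_{act}"] = var
    else:
        for act in ("L", "R"):
            out[f"AV_{act}"] = np.nan
            out[f"avar_{act}"] = np.nan

    # last-trial history variables (ObjectChoice convention: 0 = A, 1 = B)
    rew = t["reward"].to_numpy().astype(float)
    ch01 = session.choice01().astype(float)
    def back(x, k):
        return np.concatenate((np.full(k, np.nan), x[: T - k]))
    out["last_reward"] = back(rew, 1)
    out["last_choice"] = back(ch01, 1)
    out["last_rxc"] = out["last_reward"] * out["last_choice"]
    out["last_reward2"] = back(rew, 2)
    out["last_choice2"] = back(ch01, 2)
    out["last_rxc2"] = out["last_reward2"] * out["last_choice2"]

    # left/right mapping of subjective object value and risk via cue position
    a_left = (t["pos_A"].to_numpy() == "L")
    out["value_L"] = np.where(a_left, out["OVrc_A"], out["OVrc_B"])
    out["value_R"] = np.where(a_left, out["OVrc_B"], out["OVrc_A"])
    out["risk_L"] = np.where(a_left, out["var_A"], out["var_B"])
    out["risk_R"] = np.where(a_left, out["var_B"], out["var_A"])
    out["dvalue_lr"] = out["value_L"] - out["value_R"]
    out["drisk_lr"] = out["risk_L"] - out["risk_R"]

    ow = object_weights if isinstance(object_weights, HistoryWeightResults) else None
    aw = action_weights if isinstance(action_weights, HistoryWeightResults) else None
    return DecisionVariables(df=out, N=N, object_weights=ow, action_weights=aw)


def add_utility(dv: DecisionVariables, choice_fit) -> DecisionVariables:
    """Mean-variance utility per object: U = beta1 * OV_rc + beta2 * var.

    ``choice_fit`` is a fitted value/risk choice model supplying the value and
    risk weights (its ``beta_value`` and ``beta_risk`` attributes).
    """
    b1, b2 = choice_fit.beta_value, choice_fit.beta_risk
    for obj in ("A", "B"):
        dv.df[f"U_{obj}"] = b1 * dv.df[f"OVrc_{obj}"] + b2 * dv.df[f"var_{obj}"]
    return dv
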