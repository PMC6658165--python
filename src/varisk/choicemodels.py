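"""Choice models: value/risk logistic model, Rescorla-Wagner variants, comparison.

The headline choice model relates side choice to the left-right differences in
subjective object value and subjective object risk::

    log(pL/pR) = b0 + b1 (ValueLeft - ValueRight) + b2 (RiskLeft - RiskRight)

A positive fitted risk weight b2 indicates risk seeking: at equal value the
higher-risk side is chosen more often.  Model comparison pits this model
against value-only, choice-history, objective-probability and reinforcement-
learning alternatives on per-trial-normalized AIC/BIC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .behavior import (DecisionVariables, HistoryWeightModel,
                       compute_decision_variables, robust_logit)
from .task import Session

__all__ = [
    "ChoiceModel",
    "ChoiceModelResults",
    "RLModel",
    "RLResults",
    "compare_choice_models",
    "matching_analysis",
    "MatchingStats",
    "choice_psychometrics",
]


# ---------------------------------------------------------------------------
# value/risk choice model (left/right frame)
# ---------------------------------------------------------------------------

@dataclass
class ChoiceModelResults:
    """Fitted value/risk choice model."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    llf: float
    nobs: int
    model_id: str = "value_risk"

    @property
    def beta_value(self) -> float:
        return float(self.params.get("dvalue", np.nan))

    @property
    def beta_risk(self) -> float:
        return float(self.params.get("drisk", np.nan))

    @property
    def bias(self) -> float:
        return float(self.params.get("const", np.nan))

    @property
    def k(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        """Per-trial normalized AIC (mean deviance + penalty scale)."""
        return (-2.0 * self.llf + 2.0 * self.k) / self.nobs

    @property
    def bic(self) -> float:
        return (-2.0 * self.llf + self.k * np.log(self.nobs)) / self.nobs

    def summary(self) -> str:
        lines = [f"Choice model [{self.model_id}] n={self.nobs} "
                 f"llf={self.llf:.2f} AIC/n={self.aic:.4f} BIC/n={self.bic:.4f}"]
        for name in self.params.index:
            lines.append(f"  {name:>8}: {self.params[name]:9.4f} "
                         f"(se {self.bse[name]:.4f}, p={self.pvalues[name]:.3g})")
        return "\n".join(lines)


class ChoiceModel:
    """Logistic regression of side choice on value and risk differences.

    Parameters
    ----------
    dv : DecisionVariables
    session : Session
    include_risk : bool
        Drop the risk regressor to obtain the value-only variant.
    subset : {'all', 'min_dvalue'}
        ``'min_dvalue'`` restricts the fit to the lowest decile of |dValue|
        (the minimal-value-difference control).
    """

    def __init__(self, dv: DecisionVariables, session: Session,
                 include_risk: bool = True, subset: str = "all"):
        left = (session.trials["action"].to_numpy() == "L").astype(float)
        valid = dv.valid
        dval = dv.df["dvalue_lr"].to_numpy()
        drisk = dv.df["drisk_lr"].to_numpy()
        if subset == "min_dvalue":
            thr = np.nanquantile(np.abs(dval[valid]), 0.10)
            valid = valid & (np.abs(dval) <= thr)
        elif subset != "all":
            raise ValueError(f"unknown subset {subset!r}")
        X = pd.DataFrame({"const": 1.0, "dvalue": dval[valid]})
        if include_risk:
            X["drisk"] = drisk[valid]
        self.X, self.y = X, left[valid]
        self.include_risk = include_risk
        self.subset = subset

    def shared_variance(self) -> float:
        """R^2 between the value and risk difference regressors (collinearity check)."""
        if not self.include_risk:
            return np.nan
        r = np.corrcoef(self.X["dvalue"], self.X["drisk"])[0, 1]
        return float(r**2)

    def fit(self) -> ChoiceModelResults:
        params, bse, pvalues, llf, separation = robust_logit(self.y, self.X)
        mid = "value_risk" if self.include_risk else "value_only"
        if self.subset == "min_dvalue":
            mid += "/min_dvalue"
        if separation:
            mid += "/penalized"
        return ChoiceModelResults(params=params, bse=bse, pvalues=pvalues,
                                  llf=llf, nobs=len(self.y), model_id=mid)


# ---------------------------------------------------------------------------
# Rescorla-Wagner reinforcement-learning models
# ---------------------------------------------------------------------------

def _rl_nll(params_nat: dict, session: Session, variant: str,
            ll_mask: np.ndarray | None = None) -> float:
    """Negative log likelihood of object choices under an RL variant.

    Values are updated on every trial; the likelihood is summed over
    ``ll_mask`` trials (all trials by default).
    """
    alpha = params_nat["alpha"]
    tau = params_nat["tau"]
    kappa = params_nat.get("kappa", 0.0)
    ch = session.choice01()  # 0 = A, 1 = B
    rew = session.trials["reward"].to_numpy().astype(float)
    T = len(ch)
    VA, VB = 0.5, 0.5
    nll = 0.0
    use = ll_mask if ll_mask is not None else np.ones(T, dtype=bool)
    for i in range(T):
        x = tau * (VA - VB)
        # log P(A) = -log(1+e^-x); log P(B) = -log(1+e^x)
        if use[i]:
            z = x if ch[i] == 0 else -x
            # -log sigmoid(z), numerically stable
            nll += np.log1p(np.exp(-z)) if z > 0 else -z + np.log1p(np.exp(z))
        r = rew[i]
        if ch[i] == 0:
            VA += alpha * (r - VA)
            if variant == "stack":
                VB += kappa * (1.0 - VB)
            elif variant == "reversal":
                VB += alpha * ((1.0 - r) - VB)
        else:
            VB += alpha * (r - VB)
            if variant == "stack":
                VA += kappa * (1.0 - VA)
            elif variant == "reversal":
                VA += alpha * ((1.0 - r) - VA)
    return nll


@dataclass
class RLResults:
    """Fitted Rescorla-Wagner model."""

    variant: str
    alpha: float
    tau: float
    kappa: float | None
    llf: float
    nobs: int
    k: int
    converged: bool
    n_restarts: int
    alpha_se: float = np.nan
    tau_se: float = np.nan

    @property
    def aic(self) -> float:
        return (-2.0 * self.llf + 2.0 * self.k) / self.nobs

    @property
    def bic(self) -> float:
        return (-2.0 * self.llf + self.k * np.log(self.nobs)) / self.nobs

    def summary(self) -> str:
        s = (f"RL model [{self.variant}] alpha={self.alpha:.3f} "
             f"(se {self.alpha_se:.3f}) tau={self.tau:.3f} (se {self.tau_se:.3f})")
        if self.kappa is not None:
            s += f" kappa={self.kappa:.3f}"
        s += (f"\n  n={self.nobs} llf={self.llf:.2f} AIC/n={self.aic:.4f} "
              f"BIC/n={self.bic:.4f} restarts={self.n_restarts}")
        return s


class RLModel:
    """Maximum-likelihood Rescorla-Wagner model of object choice.

    ``variant='standard'`` updates only the chosen option toward the outcome;
    ``'stack'`` additionally grows the unchosen option's value toward 1 at a
    free rate (availability accumulation under baiting); ``'reversal'``
    updates the unchosen option toward the complementary outcome.  Choice
    probability is a softmax with inverse temperature ``tau`` over the two
    object values.  Parameters are estimated on an unconstrained scale
    (logit alpha/kappa, log tau) with multi-start L-BFGS-B.
    """

    def __init__(self, session: Session, variant: str = "standard",
                 burn_in: int = 0):
        if variant not in ("standard", "stack", "reversal"):
            raise ValueError(f"unknown RL variant {variant!r}")
        self.session = session
        self.variant = variant
        T = session.n_trials
        self.ll_mask = np.arange(T) >= burn_in
        self.nobs = int(self.ll_mask.sum())

    def _natural(self, theta: np.ndarray) -> dict:
        out = {"alpha": 1.0 / (1.0 + np.exp(-theta[0])),
               "tau": float(np.exp(theta[1]))}
        if self.variant == "stack":
            out["kappa"] = 1.0 / (1.0 + np.exp(-theta[2]))
        return out

    def _obj(self, theta: np.ndarray) -> float:
        return _rl_nll(self._natural(theta), self.session, self.variant,
                       self.ll_mask)

    def fit(self, n_starts: int = 3, seed: int = 0) -> RLResults:
        rng = np.random.default_rng(seed)
        k = 3 if self.variant == "stack" else 2
        starts = [np.array([0.0, 1.0, -1.0][:k], dtype=float)]
        for _ in range(n_starts - 1):
            starts.append(rng.normal(0.0, 1.5, size=k))
        bounds = [(-8.0, 8.0), (-4.0, 6.0)] + ([(-8.0, 8.0)] if k == 3 else [])
        best = None
        for th0 in starts:
            res = optimize.minimize(self._obj, np.clip(th0, -4, 4),
                                    method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
        nat = self._natural(best.x)
        a_se = t_se = np.nan
        try:
            H = _numerical_hessian(self._obj, best.x)
            cov = np.linalg.inv(H)
            # delta method back to natural scale
            a = nat["alpha"]
            a_se = float(np.sqrt(max(cov[0, 0], 0.0)) * a * (1 - a))
            t_se = float(np.sqrt(max(cov[1, 1], 0.0)) * nat["tau"])
        except np.linalg.LinAlgError:
            pass
        return RLResults(variant=self.variant, alpha=nat["alpha"],
                         tau=nat["tau"], kappa=nat.get("kappa"),
                         llf=-float(best.fun), nobs=self.nobs, k=k,
                         converged=bool(best.success), n_restarts=len(starts),
                         alpha_se=a_se, tau_se=t_se)


def _numerical_hessian(f, x, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.eye(n)[i] * eps
            ej = np.eye(n)[j] * eps
            H[i, j] = H[j, i] = (f(x + ei + ej) - f(x + ei - ej)
                                 - f(x - ei + ej) + f(x - ei - ej)) / (4 * eps**2)
    return H


# ---------------------------------------------------------------------------
# model comparison (11-model table)
# ---------------------------------------------------------------------------

MODEL_DESCRIPTIONS = {
    1: "Value from reward history",
    2: "Value from reward history and risk",
    3: "Value from choice history",
    4: "Value from choice history and risk",
    5: "Value from reward and choice history",
    6: "Value from reward and choice history and risk",
    7: "Objective reward probabilities",
    8: "Objective reward probabilities and objective risk",
    9: "Reinforcement learning (RL) model",
    10: "RL with stack parameter",
    11: "RL, reversal-learning variant",
}


def _lr_map(session: Session, col_A: np.ndarray, col_B: np.ndarray):
    a_left = session.trials["pos_A"].to_numpy() == "L"
    left = np.where(a_left, col_A, col_B)
    right = np.where(a_left, col_B, col_A)
    return left - right


def compare_choice_models(session: Session, N: int = 10,
                          weights=None, rl_starts: int = 3,
                          rl_seed: int = 0) -> pd.DataFrame:
    """Fit all 11 candidate choice models and rank them by per-trial AIC.

    Models 1-8 are logistic regressions of side choice on left-right
    differences of the respective decision variables (with a side-bias
    intercept); models 9-11 are RL variants in the object frame.  All
    likelihoods are evaluated over the post-burn-in trials, making per-trial
    AIC/BIC comparable across models.  ``weights`` optionally injects a
    history weight set; otherwise one is fitted from the session.
    """
    if weights is None:
        weights = HistoryWeightModel(session, N=N, domain="object").fit()
    dv = compute_decision_variables(session, weights, N=N)
    d = dv.df
    valid = dv.valid
    left = (session.trials["action"].to_numpy() == "L").astype(float)

    def diff(a, b):
        return _lr_map(session, d[a].to_numpy(), d[b].to_numpy())

    regs = {
        1: {"dOVr": diff("OVr_A", "OVr_B")},
        2: {"dOVr": diff("OVr_A", "OVr_B"), "drisk": diff("var_A", "var_B")},
        3: {"dOVc": diff("OVc_A", "OVc_B")},
        4: {"dOVc": diff("OVc_A", "OVc_B"), "drisk": diff("var_A", "var_B")},
        5: {"dvalue": diff("OVrc_A", "OVrc_B")},
        6: {"dvalue": diff("OVrc_A", "OVrc_B"), "drisk": diff("var_A", "var_B")},
        7: {"dprob": diff("true_p_A", "true_p_B")},
        8: {"dprob": diff("true_p_A", "true_p_B"),
            "dtrisk": diff("true_risk_A", "true_risk_B")},
    }

    rows = []
    n = int(valid.sum())
    for mid, cols in regs.items():
        X = pd.DataFrame({k: v[valid] for k, v in cols.items()})
        X.insert(0, "const", 1.0)
        _, _, _, llf, _ = robust_logit(left[valid], X)
        k = X.shape[1]
        rows.append({"model": mid, "description": MODEL_DESCRIPTIONS[mid],
                     "k": k, "llf": llf,
                     "aic": (-2 * llf + 2 * k) / n,
                     "bic": (-2 * llf + k * np.log(n)) / n})

    for mid, variant in ((9, "standard"), (10, "stack"), (11, "reversal")):
        fit = RLModel(session, variant, burn_in=N).fit(n_starts=rl_starts,
                                                       seed=rl_seed)
        rows.append({"model": mid, "description": MODEL_DESCRIPTIONS[mid],
                     "k": fit.k, "llf": fit.llf, "aic": fit.aic, "bic": fit.bic})

    table = pd.DataFrame(rows).set_index("model")
    table["best"] = table["aic"] == table["aic"].min()
    return table


# ---------------------------------------------------------------------------
# matching behavior summaries
# ---------------------------------------------------------------------------

@dataclass
class MatchingStats:
    """Block-wise matching regression and sliding-window matching trace."""

    block_table: pd.DataFrame
    slope: float
    intercept: float
    r2: float
    degenerate: bool
    sliding: pd.DataFrame

    def summary(self) -> str:
        if self.degenerate:
            return "Matching regression degenerate (exclusive preference)."
        return (f"Matching: log choice ratio = {self.slope:.3f} * log reward "
                f"ratio + {self.intercept:.3f} (R^2={self.r2:.3f}, "
                f"{len(self.block_table)} blocks)")


def matching_analysis(session: Session, window: int = 7) -> MatchingStats:
    """Matching-law summaries of a session.

    Per block: log choice ratio vs log reward ratio (0.5 additive smoothing
    for zero counts) with an OLS regression across blocks; plus a sliding
    ``window``-trial correlation-style trace of choice fraction and reward
    fraction, and cumulative choice counts for choice-trajectory plots.
    """
    t = session.trials
    rows = []
    for b, g in t.groupby("block_id"):
        nA = float((g["choice"] == "A").sum())
        nB = float((g["choice"] == "B").sum())
        rA = float(((g["choice"] == "A") & (g["reward"] == 1)).sum())
        rB = float(((g["choice"] == "B") & (g["reward"] == 1)).sum())
        rows.append({"block_id": b, "n_trials": len(g), "nA": nA, "nB": nB,
                     "rA": rA, "rB": rB,
                     "log_choice_ratio": np.log((nA + 0.5) / (nB + 0.5)),
                     "log_reward_ratio": np.log((rA + 0.5) / (rB + 0.5)),
                     "base_p_A": g["base_p_A"].iloc[0],
                     "base_p_B": g["base_p_B"].iloc[0]})
    bt = pd.DataFrame(rows)

    degenerate = bool((bt["nA"] == 0).all() or (bt["nB"] == 0).all()
                      or bt["log_reward_ratio"].std() == 0)
    if degenerate or len(bt) < 2:
        slope = intercept = r2 = np.nan
        degenerate = True
    else:
        X = sm.add_constant(bt["log_reward_ratio"])
        res = sm.OLS(bt["log_choice_ratio"], X).fit()
        slope = float(res.params["log_reward_ratio"])
        intercept = float(res.params["const"])
        r2 = float(res.rsquared)

    ch = (t["choice"] == "A").astype(float).to_numpy()
    rw = ((t["choice"] == "A") & (t["reward"] == 1)).astype(float).to_numpy()
    rwB = ((t["choice"] == "B") & (t["reward"] == 1)).astype(float).to_numpy()
    kern = np.ones(window)
    cA = np.convolve(ch, kern, mode="valid")
    rA_s = np.convolve(rw, kern, mode="valid")
    rB_s = np.convolve(rwB, kern, mode="valid")
    with np.errstate(invalid="ignore", divide="ignore"):
        choice_frac = cA / window
        reward_frac = rA_s / np.maximum(rA_s + rB_s, 1e-12)
    sliding = pd.DataFrame({
        "trial": t["trial"].to_numpy()[window - 1:],
        "choice_frac_A": choice_frac,
        "reward_frac_A": reward_frac,
        "block_id": t["block_id"].to_numpy()[window - 1:],
    })
    return MatchingStats(block_table=bt, slope=slope, intercept=intercept,
                         r2=r2, degenerate=degenerate, sliding=sliding)


# ---------------------------------------------------------------------------
# psychometrics
# ---------------------------------------------------------------------------

def choice_psychometrics(dv: DecisionVariables, session: Session,
                         n_value_bins: int = 4) -> dict:
    """Choice probability by value-difference bins crossed with a risk median split.

    Works in the object frame (A - B differences).  Returns the binned table,
    chi-square tests comparing the low/high risk split within each value bin,
    and marginal psychometric curves vs value and risk difference.
    """
    d = dv.df
    valid = dv.valid
    dval = (d["OVrc_A"] - d["OVrc_B"]).to_numpy()[valid]
    drisk = (d["var_A"] - d["var_B"]).to_numpy()[valid]
    choseA = (session.trials["choice"].to_numpy() == "A")[valid].astype(int)

    qs = np.unique(np.quantile(dval, np.linspace(0, 1, n_value_bins + 1)))
    n_value_bins = max(len(qs) - 1, 1)
    vbin = np.digitize(dval, qs[1:-1])
    # risk median split computed within each value bin, so the split is not
    # confounded by the value-risk correlation
    rsplit = np.zeros(len(drisk), dtype=int)
    for b in range(n_value_bins):
        m = vbin == b
        if m.any():
            rsplit[m] = (drisk[m] > np.median(drisk[m])).astype(int)

    rows, tests = [], []
    for b in range(n_value_bins):
        for s in (0, 1):
            m = (vbin == b) & (rsplit == s)
            rows.append({"value_bin": b, "risk_split": "high" if s else "low",
                         "n": int(m.sum()),
                         "p_choose_A": float(choseA[m].mean()) if m.any() else np.nan,
                         "empty": not m.any()})
        lo = (vbin == b) & (rsplit == 0)
        hi = (vbin == b) & (rsplit == 1)
        if lo.sum() > 0 and hi.sum() > 0:
            table = np.array([[choseA[lo].sum(), lo.sum() - choseA[lo].sum()],
                              [choseA[hi].sum(), hi.sum() - choseA[hi].sum()]])
            if (table.sum(axis=1) > 0).all() and (table.sum(axis=0) > 0).all():
                chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            else:
                chi2, p = np.nan, np.nan
        else:
            chi2, p = np.nan, np.nan
        tests.append({"value_bin": b, "chi2": chi2, "p": p})

    def curve(x, nbins=8):
        q = np.quantile(x, np.linspace(0, 1, nbins + 1))
        q[0] -= 1e-9
        bins = np.digitize(x, q[1:-1])
        return pd.DataFrame({
            "bin_center": [float(x[bins == b].mean()) for b in range(nbins)],
            "p_choose_A": [float(choseA[bins == b].mean()) if (bins == b).any()
                           else np.nan for b in range(nbins)],
            "n": [int((bins == b).sum()) for b in range(nbins)],
        })

    return {"binned": pd.DataFrame(rows), "tests": pd.DataFrame(tests),
            "curve_value": curve(dval), "curve_risk": curve(drisk)}
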