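"""Single-neuron analysis battery for risk coding.

Pipeline on each recorded (or simulated) neuron:

1. Count impulses in the 11 fixed 500-ms task epochs.
2. Screen for task-relatedness against the Pre-fix control period
   (paired Wilcoxon, p < 0.005 Bonferroni-corrected over the 10 test epochs).
3. Multiple linear regression of trial-by-trial impulse rate on task and
   decision variables (several regressor sets: objective risk, subjective
   risk, last-trial history, two-trial history, action risk, stepwise
   competition sets, utility control); a response codes object (action) risk
   if either risk regressor is significant (t-test, p < 0.05).
4. Axis-invariant classification from the polar angle of the two risk
   coefficients into object-A risk, object-B risk, risk sum and risk
   difference (eight 45-degree segments).
5. Sliding-window regression (200-ms windows, 25-ms steps) with a
   shuffle-calibrated run criterion (> 6 consecutive significant windows),
   coding latencies, joint-coding statistics, and non-stationarity controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._stats import dependent_proportions_ztest, first_run_start
from .behavior import DecisionVariables
from .neurons import EPOCH_DURATION_S, EpochCounts
from .task import EPOCHS, EPOCH_NAMES, Session
from .variables import variable_frame

__all__ = [
    "MODEL_REGRESSORS",
    "RISK_REGRESSORS",
    "DEFAULT_SEGMENTS",
    "count_epochs",
    "task_relatedness",
    "ResponseRegression",
    "ResponseFit",
    "angle_classification",
    "CodingLabel",
    "stepwise_regression",
    "partial_F",
    "partial_F_choice",
    "sliding_window_regression",
    "SlidingWindowResult",
    "sliding_shuffle_calibration",
    "coding_latency",
    "population_value_curve",
    "risk_updating_analysis",
    "nonstationarity_controls",
    "joint_coding_stats",
]

#: Regressor sets of the fixed-window response models.
MODEL_REGRESSORS: dict[str, list[str]] = {
    "objective_risk": ["choice", "cue_position", "action",
            "true_prob_A", "true_prob_B", "true_risk_A", "true_risk_B"],
    "subjective_risk": ["choice", "cue_position", "action",
             "object_value_A", "object_value_B", "object_risk_A", "object_risk_B"],
    "history": ["choice", "cue_position", "action",
             "object_value_A", "object_value_B", "object_risk_A", "object_risk_B",
             "last_reward", "last_choice", "last_rxc"],
    "history2": ["choice", "cue_position", "action",
             "object_value_A", "object_value_B", "object_risk_A", "object_risk_B",
             "last_reward", "last_choice", "last_rxc",
             "last_reward2", "last_choice2", "last_rxc2"],
    "risk_competition": ["choice", "cue_position", "action",
             "object_value_A", "object_value_B", "object_risk_A", "object_risk_B",
             "true_prob_A", "true_prob_B", "true_risk_A", "true_risk_B"],
    "action_risk_model": ["choice", "cue_position", "action",
             "action_value_L", "action_value_R", "action_risk_L", "action_risk_R"],
    "object_action_competition": ["choice", "cue_position", "action",
             "object_value_A", "object_value_B", "object_risk_A", "object_risk_B",
             "action_value_L", "action_value_R", "action_risk_L", "action_risk_R"],
    "utility": ["choice", "cue_position", "action",
                "utility_A", "utility_B", "object_risk_A", "object_risk_B"],
}

#: The risk regressors whose significance defines risk coding, per model.
RISK_REGRESSORS: dict[str, tuple[str, str]] = {
    "objective_risk": ("true_risk_A", "true_risk_B"),
    "subjective_risk": ("object_risk_A", "object_risk_B"),
    "history": ("object_risk_A", "object_risk_B"),
    "history2": ("object_risk_A", "object_risk_B"),
    "risk_competition": ("object_risk_A", "object_risk_B"),
    "action_risk_model": ("action_risk_L", "action_risk_R"),
    "object_action_competition": ("object_risk_A", "object_risk_B"),
    "utility": ("object_risk_A", "object_risk_B"),
}


# ---------------------------------------------------------------------------
# epoch counting and task-relatedness
# ---------------------------------------------------------------------------

def count_epochs(spike_times: pd.DataFrame, session: Session,
                 neuron_ids: list[str] | None = None) -> EpochCounts:
    """Bin event-aligned spike times into the 11 canonical epochs.

    ``spike_times`` is long format (``neuron, trial, t_ms``, trial-relative
    times).  Trials missing from the spike table contribute zero counts.
    """
    trials = session.trials
    T = len(trials)
    if neuron_ids is None:
        neuron_ids = list(pd.unique(spike_times["neuron"]))
    # absolute epoch windows per trial
    starts = np.empty((T, len(EPOCHS)))
    for e, (name, event, off, dur) in enumerate(EPOCHS):
        starts[:, e] = trials[f"t_{event}"].to_numpy() + off
    counts = np.zeros((len(neuron_ids), T, len(EPOCHS)), dtype=int)
    idx_of = {nid: i for i, nid in enumerate(neuron_ids)}
    for (nid, tr), g in spike_times.groupby(["neuron", "trial"], sort=False):
        if nid not in idx_of:
            continue
        ti = int(tr) - 1
        st = np.sort(g["t_ms"].to_numpy())
        for e in range(len(EPOCHS)):
            a = starts[ti, e]
            counts[idx_of[nid], ti, e] = int(
                np.searchsorted(st, a + 500.0, side="left")
                - np.searchsorted(st, a, side="left"))
    return EpochCounts(counts=counts, neuron_ids=list(neuron_ids))


def task_relatedness(counts: EpochCounts, alpha: float = 0.005,
                     control: str = "Pre-fix") -> pd.DataFrame:
    """Per-(neuron, epoch) task-relatedness flags.

    Paired Wilcoxon signed-rank of each epoch's counts against the control
    period on the same trials, two-sided, Bonferroni-corrected over the 10
    non-control epochs (threshold alpha / 10).  The control epoch itself is
    always admitted.  Zero-variance differences are non-significant.
    """
    ci = counts.epoch_index(control)
    n_tests = len(counts.epoch_names) - 1
    rows = []
    for i, nid in enumerate(counts.neuron_ids):
        ctrl = counts.counts[i, :, ci].astype(float)
        for e, name in enumerate(counts.epoch_names):
            if e == ci:
                rows.append({"neuron": nid, "epoch": name, "p": 0.0,
                             "task_related": True})
                continue
            diff = counts.counts[i, :, e].astype(float) - ctrl
            if np.all(diff == 0):
                p = 1.0
            else:
                p = float(stats.wilcoxon(diff).pvalue)
            rows.append({"neuron": nid, "epoch": name, "p": p,
                         "task_related": p < alpha / n_tests})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixed-window response regressions
# ---------------------------------------------------------------------------

@dataclass
class ResponseFit:
    """OLS fit of one neuronal response (neuron x epoch) on one regressor set."""

    neuron: str
    epoch: str
    model_id: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    std_params: pd.Series
    partial_r2: pd.Series
    f_stat: float
    f_pvalue: float
    rsquared: float
    nobs: int
    ssr: float
    flagged: list = field(default_factory=list)

    @property
    def codes_risk(self) -> bool:
        """Significant (p < 0.05) coefficient for either risk regressor."""
        a, b = RISK_REGRESSORS[self.model_id]
        return bool((self.pvalues.get(a, 1.0) < 0.05)
                    or (self.pvalues.get(b, 1.0) < 0.05))

    def codes(self, regressor: str, alpha: float = 0.05) -> bool:
        return bool(self.pvalues.get(regressor, 1.0) < alpha)

    def summary(self) -> str:
        lines = [f"Response {self.neuron}/{self.epoch} [{self.model_id}] "
                 f"R^2={self.rsquared:.3f} F={self.f_stat:.2f} "
                 f"(p={self.f_pvalue:.3g}) n={self.nobs}"]
        for name in self.params.index:
            lines.append(f"  {name:>16}: b={self.params[name]:8.4f} "
                         f"std={self.std_params[name]:7.4f} "
                         f"pR2={self.partial_r2[name]:6.4f} "
                         f"p={self.pvalues[name]:.3g}")
        return "\n".join(lines)


def _ols_response(y: np.ndarray, X: pd.DataFrame) -> sm.regression.linear_model.RegressionResults:
    return sm.OLS(y, X).fit()


def _fit_frame(y: np.ndarray, X: pd.DataFrame, neuron: str, epoch: str,
               model_id: str) -> ResponseFit:
    flagged = []
    keep = list(X.columns)
    # rank check: flag (not drop) collinear regressors
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.drop(columns="const", errors="ignore")
        flagged = [c for c in corr.columns if corr[c].std() == 0]
    res = _ols_response(y, X)
    sy = np.std(y, ddof=1)
    std = {}
    pr2 = {}
    df_resid = res.df_resid
    for c in X.columns:
        sx = np.std(X[c].to_numpy(), ddof=1)
        std[c] = float(res.params[c] * sx / sy) if sy > 0 else np.nan
        if c == "const":
            pr2[c] = np.nan
            continue
        t = res.tvalues[c]
        # equivalent to (SSE_reduced - SSE_full) / SSE_reduced for one regressor
        pr2[c] = float(t**2 / (t**2 + df_resid)) if np.isfinite(t) else np.nan
    return ResponseFit(
        neuron=neuron, epoch=epoch, model_id=model_id,
        params=res.params, bse=res.bse, pvalues=res.pvalues,
        std_params=pd.Series(std), partial_r2=pd.Series(pr2),
        f_stat=float(res.fvalue), f_pvalue=float(res.f_pvalue),
        rsquared=float(res.rsquared), nobs=int(res.nobs),
        ssr=float(res.ssr), flagged=flagged)


class ResponseRegression:
    """Multiple linear regression of epoch impulse rates on task variables.

    Statsmodels-flavoured: construct from data, call :meth:`fit` for one
    response or :meth:`fit_all` for the population.

    Parameters
    ----------
    counts : EpochCounts
    session : Session
    dv : DecisionVariables
    model : str
        One of ``objective_risk, subjective_risk, history, history2, risk_competition, action_risk_model, object_action_competition, utility``.
    """

    def __init__(self, counts: EpochCounts, session: Session,
                 dv: DecisionVariables, model: str = "subjective_risk"):
        if model not in MODEL_REGRESSORS:
            raise ValueError(f"unknown model {model!r}")
        self.counts = counts
        self.session = session
        self.model = model
        frame = variable_frame(session, dv)
        cols = MODEL_REGRESSORS[model]
        missing = [c for c in cols if c not in frame.columns]
        if missing:
            raise ValueError(f"regressors not available: {missing} "
                             "(utility requires add_utility first)")
        X = frame[cols].copy()
        ok = ~X.isna().any(axis=1)
        self.valid = ok.to_numpy() & dv.valid
        X = X.loc[self.valid]
        X.insert(0, "const", 1.0)
        self.X = X.reset_index(drop=True)

    def _y(self, neuron_idx: int, epoch_idx: int) -> np.ndarray:
        return (self.counts.counts[neuron_idx, self.valid, epoch_idx]
                / EPOCH_DURATION_S)

    def fit(self, neuron: str | int, epoch: str) -> ResponseFit:
        ni = (neuron if isinstance(neuron, int)
              else self.counts.neuron_ids.index(neuron))
        ei = self.counts.epoch_index(epoch)
        y = self._y(ni, ei)
        return _fit_frame(y, self.X, self.counts.neuron_ids[ni], epoch,
                          self.model)

    def fit_all(self, relatedness: pd.DataFrame | None = None) -> list[ResponseFit]:
        """Fit every (neuron, epoch) response, optionally restricted to
        task-related responses (output of :func:`task_relatedness`)."""
        admit = None
        if relatedness is not None:
            admit = {(r.neuron, r.epoch) for r in relatedness.itertuples()
                     if r.task_related}
        fits = []
        for ni, nid in enumerate(self.counts.neuron_ids):
            for epoch in self.counts.epoch_names:
                if admit is not None and (nid, epoch) not in admit:
                    continue
                fits.append(self.fit(ni, epoch))
        return fits


def results_table(fits: list[ResponseFit]) -> pd.DataFrame:
    """Flatten a list of response fits into a tidy per-response table."""
    rows = []
    for f in fits:
        row = {"neuron": f.neuron, "epoch": f.epoch, "model": f.model_id,
               "rsquared": f.rsquared, "f_pvalue": f.f_pvalue,
               "codes_risk": f.codes_risk}
        for c in f.params.index:
            row[f"b_{c}"] = f.params[c]
            row[f"p_{c}"] = f.pvalues[c]
            row[f"std_{c}"] = f.std_params[c]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# angle classification
# ---------------------------------------------------------------------------

_ANGLE_CATEGORIES = {0: "risk_1", 45: "risk_sum", 90: "risk_2",
                     135: "risk_diff", 180: "risk_1", 225: "risk_sum",
                     270: "risk_2", 315: "risk_diff"}


@dataclass
class CodingLabel:
    """Axis-invariant risk-coding category from the coefficient angle."""

    neuron: str
    epoch: str
    category: str
    angle: float
    significant: bool
    beta1: float
    beta2: float
    f_pvalue: float


def angle_classification(y: np.ndarray, risk1: np.ndarray, risk2: np.ndarray,
                         neuron: str = "", epoch: str = "",
                         labels: tuple[str, str] = ("A", "B")) -> CodingLabel:
    """Classify a response by the polar angle of its two risk coefficients.

    Fits ``y = b0 + b1 risk1 + b2 risk2``.  If the overall F-test is
    significant (p < 0.05) the angle of (b1, b2) assigns the response to one
    of eight 45-degree segments: segments toward 0/180 degrees code risk of
    the first alternative, 90/270 the second, 45/225 risk sum, 135/315 risk
    difference.  Segments are half-open ``[center - 22.5, center + 22.5)``.
    A zero coefficient vector is unclassifiable.
    """
    X = pd.DataFrame({"const": 1.0, "r1": risk1, "r2": risk2})
    res = sm.OLS(np.asarray(y, dtype=float), X).fit()
    b1, b2 = float(res.params["r1"]), float(res.params["r2"])
    sig = bool(res.f_pvalue < 0.05)
    if b1 == 0.0 and b2 == 0.0:
        return CodingLabel(neuron, epoch, "unclassifiable", np.nan, sig,
                           b1, b2, float(res.f_pvalue))
    angle = float(np.degrees(np.arctan2(b2, b1)) % 360.0)
    center = int(np.floor(((angle + 22.5) % 360.0) / 45.0)) * 45
    cat = _ANGLE_CATEGORIES[center]
    cat = {"risk_1": f"risk_{labels[0]}", "risk_2": f"risk_{labels[1]}"}.get(cat, cat)
    if not sig:
        cat = "none"
    return CodingLabel(neuron, epoch, cat, angle, sig, b1, b2,
                       float(res.f_pvalue))


# ---------------------------------------------------------------------------
# stepwise regression and partial F tests
# ---------------------------------------------------------------------------

def stepwise_regression(y: np.ndarray, X: pd.DataFrame,
                        entry_p: float = 0.05, removal_p: float = 0.10):
    """Forward-entry / backward-removal stepwise OLS.

    Starts from the intercept-only model; at each step the candidate with the
    smallest entry p-value below ``entry_p`` is added, then any retained
    regressor whose p-value exceeds ``removal_p`` is removed.  Returns
    ``(retained, final_fit)`` where ``retained`` is the ordered list of
    retained regressor names and ``final_fit`` the statsmodels OLS result.
    """
    y = np.asarray(y, dtype=float)
    candidates = [c for c in X.columns if c != "const"]

    def design(cols):
        Xc = X[cols].copy()
        Xc.insert(0, "const", 1.0)
        return Xc

    retained: list[str] = []
    while True:
        # forward step
        best_p, best_c = None, None
        for c in candidates:
            if c in retained:
                continue
            res = sm.OLS(y, design(retained + [c])).fit()
            p = res.pvalues[c]
            if np.isfinite(p) and p < entry_p and (best_p is None or p < best_p):
                best_p, best_c = p, c
        if best_c is None:
            break
        retained.append(best_c)
        # backward step
        while retained:
            res = sm.OLS(y, design(retained)).fit()
            worst = max(retained, key=lambda c: res.pvalues[c])
            if res.pvalues[worst] >= removal_p:
                retained.remove(worst)
            else:
                break
        if not retained:
            break
    final = sm.OLS(y, design(retained)).fit()
    return retained, final


def partial_F(y: np.ndarray, X_full: pd.DataFrame, X_reduced: pd.DataFrame):
    """Partial F-test of nested OLS models; returns (F, p)."""
    y = np.asarray(y, dtype=float)
    full = sm.OLS(y, X_full).fit()
    red = sm.OLS(y, X_reduced).fit()
    ddf = X_full.shape[1] - X_reduced.shape[1]
    if ddf <= 0:
        raise ValueError("models are not nested (full must have more regressors)")
    num = (red.ssr - full.ssr) / ddf
    den = full.ssr / full.df_resid
    if den == 0 or num <= 0:
        return 0.0, 1.0
    F = num / den
    p = float(stats.f.sf(F, ddf, full.df_resid))
    return float(F), p


def partial_F_choice(reg: ResponseRegression, neuron: str | int, epoch: str,
                     regressor: str = "choice"):
    """Does a distinct choice regressor improve the response model?

    Compares the model with vs without ``regressor``; returns (F, p).
    """
    ni = (neuron if isinstance(neuron, int)
          else reg.counts.neuron_ids.index(neuron))
    ei = reg.counts.epoch_index(epoch)
    y = reg._y(ni, ei)
    return partial_F(y, reg.X, reg.X.drop(columns=[regressor]))


# ---------------------------------------------------------------------------
# sliding-window regression
# ---------------------------------------------------------------------------

def _window_counts(spike_times: pd.DataFrame, session: Session, neuron: str,
                   align_event: str, t_start: float, t_stop: float,
                   width: float, step: float):
    """(trials x windows) spike-count matrix aligned to ``align_event``."""
    trials = session.trials
    T = len(trials)
    w_starts = np.arange(t_start, t_stop - width + 1e-9, step)
    Y = np.zeros((T, len(w_starts)))
    sub = spike_times[spike_times["neuron"] == neuron]
    ev = trials[f"t_{align_event}"].to_numpy()
    for tr, g in sub.groupby("trial", sort=False):
        ti = int(tr) - 1
        rel = np.sort(g["t_ms"].to_numpy() - ev[ti])
        Y[ti] = (np.searchsorted(rel, w_starts + width, side="left")
                 - np.searchsorted(rel, w_starts, side="left"))
    return Y, w_starts


def _ols_grid(X: np.ndarray, Y: np.ndarray):
    """Vectorized OLS of many responses (columns of Y) on one design X.

    Returns (betas k x W, pvalues k x W) with two-sided t-tests.
    """
    n, k = X.shape
    pinv = np.linalg.pinv(X)
    B = pinv @ Y                      # (k, W)
    resid = Y - X @ B
    dof = n - k
    s2 = (resid**2).sum(axis=0) / dof  # (W,)
    XtX_inv_diag = np.sum(pinv**2, axis=1)  # diag of (X'X)^-1
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.outer(XtX_inv_diag, s2))
        tvals = np.where(se > 0, B / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    return B, tvals, pvals


#: Event-aligned segments tiling the trial for sliding-window analyses,
#: (align_event, t_start_ms, t_stop_ms).  Each segment stays within one task
#: phase on every trial given the task's event-time jitters.
DEFAULT_SEGMENTS: tuple = (
    ("fix_on", -500.0, 1000.0),
    ("cue_on", -500.0, 500.0),
    ("fix_off", 0.0, 500.0),
    ("cue_off", -500.0, 500.0),
    ("outcome", -500.0, 1000.0),
)


@dataclass
class SlidingWindowResult:
    """Time-resolved regression of one neuron."""

    neuron: str
    window_starts: np.ndarray
    betas: pd.DataFrame       # regressor x window
    pvalues: pd.DataFrame
    cpd: pd.DataFrame         # coefficient of partial determination
    run_criterion: int
    alpha: float

    def coded(self, variable: str) -> bool:
        """True if > run_criterion consecutive windows are significant."""
        return self.latency(variable) is not None

    def latency(self, variable: str) -> float | None:
        """Start time (ms) of the first qualifying significant run."""
        mask = self.pvalues.loc[variable].to_numpy() < self.alpha
        i = first_run_start(mask, self.run_criterion)
        return None if i is None else float(self.window_starts[i])


def sliding_window_regression(spike_times: pd.DataFrame, session: Session,
                              dv: DecisionVariables, neuron: str,
                              model: str = "history",
                              align_event: str = "fix_on",
                              t_start: float = -500.0, t_stop: float = 1000.0,
                              width: float = 200.0, step: float = 25.0,
                              alpha: float = 0.05,
                              run_criterion: int = 6) -> SlidingWindowResult:
    """Sliding-window multiple regression of one neuron's spike counts.

    200-ms windows stepped by 25 ms (defaults) aligned to ``align_event``;
    each window is regressed on the ``model`` regressor set and a variable
    counts as coded when more than ``run_criterion`` consecutive windows are
    significant at ``alpha`` (the shuffle-calibrated criterion).  Windows
    with zero spikes across all trials are skipped (p = 1 there).

    Windows are slid within one event-aligned segment; the default covers
    the fixation segment (-500 to +1000 ms around fixation onset), the
    longest span over which every trial is in the same task phase given the
    event-time jitters.  Run the function once per segment (see
    ``DEFAULT_SEGMENTS``) to tile the trial; significance runs never cross
    segment boundaries.
    """
    frame = variable_frame(session, dv)
    cols = MODEL_REGRESSORS[model]
    ok = ~frame[cols].isna().any(axis=1).to_numpy() & dv.valid
    Y, w_starts = _window_counts(spike_times, session, neuron, align_event,
                                 t_start, t_stop, width, step)
    Y = Y[ok]
    X = np.column_stack([np.ones(ok.sum())] + [frame[c].to_numpy()[ok]
                                               for c in cols])
    B, tvals, P = _ols_grid(X, Y)
    empty = Y.sum(axis=0) == 0
    P[:, empty] = 1.0
    # CPD from t-statistics: t^2 / (t^2 + dof)
    dof = X.shape[0] - X.shape[1]
    cpd = tvals**2 / (tvals**2 + dof)
    names = ["const"] + cols
    return SlidingWindowResult(
        neuron=neuron, window_starts=w_starts,
        betas=pd.DataFrame(B, index=names, columns=w_starts),
        pvalues=pd.DataFrame(P, index=names, columns=w_starts),
        cpd=pd.DataFrame(cpd, index=names, columns=w_starts),
        run_criterion=run_criterion, alpha=alpha)


def sliding_shuffle_calibration(spike_times: pd.DataFrame, session: Session,
                                dv: DecisionVariables, neuron: str,
                                rng: np.random.Generator,
                                variable: str = "object_risk_A",
                                n_shuffles: int = 200, model: str = "history",
                                align_event: str = "fix_on",
                                t_start: float = -500.0, t_stop: float = 1000.0,
                                width: float = 200.0, step: float = 25.0,
                                alpha: float = 0.05,
                                run_criterion: int = 6) -> float:
    """Fraction of trial-shuffled replicates passing the run criterion.

    The response labels (window-count rows) are permuted across trials while
    the regressors stay fixed, reproducing the calibration from which the
    > ``run_criterion``-consecutive-windows rule is derived.
    """
    frame = variable_frame(session, dv)
    cols = MODEL_REGRESSORS[model]
    ok = ~frame[cols].isna().any(axis=1).to_numpy() & dv.valid
    Y, _ = _window_counts(spike_times, session, neuron, align_event,
                          t_start, t_stop, width, step)
    Y = Y[ok]
    X = np.column_stack([np.ones(ok.sum())] + [frame[c].to_numpy()[ok]
                                               for c in cols])
    vi = (["const"] + cols).index(variable)
    n_pass = 0
    for _ in range(n_shuffles):
        perm = rng.permutation(Y.shape[0])
        _, _, P = _ols_grid(X, Y[perm])
        if first_run_start(P[vi] < alpha, run_criterion) is not None:
            n_pass += 1
    return n_pass / n_shuffles


def coding_latency(results: list[SlidingWindowResult],
                   variables: list[str]) -> dict:
    """Per-variable latencies across neurons plus rank-sum comparisons.

    Returns ``{"latencies": DataFrame, "comparisons": DataFrame}``; the
    latency of a variable in a neuron is the start of its first qualifying
    run (missing when the criterion is never met).
    """
    rows = []
    for r in results:
        row = {"neuron": r.neuron}
        for v in variables:
            lat = r.latency(v)
            row[v] = np.nan if lat is None else lat
        rows.append(row)
    lat = pd.DataFrame(rows).set_index("neuron")
    comps = []
    for i, v1 in enumerate(variables):
        for v2 in variables[i + 1:]:
            a = lat[v1].dropna()
            b = lat[v2].dropna()
            if len(a) and len(b):
                u, p = stats.ranksums(a, b)
            else:
                u, p = np.nan, np.nan
            comps.append({"var1": v1, "var2": v2,
                          "median1": a.median() if len(a) else np.nan,
                          "median2": b.median() if len(b) else np.nan,
                          "stat": u, "p": p})
    return {"latencies": lat, "comparisons": pd.DataFrame(comps)}


# ---------------------------------------------------------------------------
# population summaries
# ---------------------------------------------------------------------------

def _control_zscores(counts: EpochCounts, epoch: str,
                     control: str = "Pre-fix") -> np.ndarray:
    """Per-neuron z-scores of epoch activity against the control period."""
    ei = counts.epoch_index(epoch)
    ci = counts.epoch_index(control)
    act = counts.counts[:, :, ei].astype(float)
    mu = counts.counts[:, :, ci].mean(axis=1, keepdims=True)
    sd = counts.counts[:, :, ci].std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (act - mu) / sd


def population_value_curve(counts: EpochCounts, value: np.ndarray,
                           valid: np.ndarray, epoch: str = "Cue",
                           sign_var: np.ndarray | None = None,
                           n_bins: int = 5,
                           control: str = "Pre-fix") -> pd.DataFrame:
    """Normalized population activity as a function of value bins.

    Activity is z-scored against the control period per neuron and
    sign-corrected by the sign of each neuron's regression slope on
    ``sign_var`` (default: on ``value``), then averaged within
    equal-population value bins.  Risk-tuned populations produce a
    single-peaked (inverted-U) curve over the value range; value-tuned
    populations a monotone one.
    """
    z = _control_zscores(counts, epoch, control)[:, valid]
    v = np.asarray(value, dtype=float)[valid]
    sv = v if sign_var is None else np.asarray(sign_var, dtype=float)[valid]
    signs = np.ones(z.shape[0])
    for i in range(z.shape[0]):
        slope = np.polyfit(sv, z[i], 1)[0]
        signs[i] = -1.0 if slope < 0 else 1.0
    zc = z * signs[:, None]
    qs = np.unique(np.quantile(v, np.linspace(0, 1, n_bins + 1)))
    n_bins = max(len(qs) - 1, 1)  # ties can collapse bins
    bins = np.digitize(v, qs[1:-1])
    rows = []
    for b in range(n_bins):
        m = bins == b
        if not m.any():
            rows.append({"bin": b, "value": np.nan, "mean_z": np.nan,
                         "sem_z": np.nan, "n_trials": 0, "empty": True})
            continue
        per_neuron = zc[:, m].mean(axis=1)
        rows.append({"bin": b, "value": float(v[m].mean()),
                     "mean_z": float(per_neuron.mean()),
                     "sem_z": float(per_neuron.std(ddof=1)
                                    / np.sqrt(len(per_neuron))),
                     "n_trials": int(m.sum()), "empty": False})
    return pd.DataFrame(rows)


def risk_updating_analysis(counts: EpochCounts, risk_matrix: np.ndarray,
                           rewarded: np.ndarray, valid: np.ndarray,
                           signs: np.ndarray | None = None,
                           epoch: str = "Cue",
                           control: str = "Pre-fix") -> dict:
    """Trial-N vs trial-N-1 activity contrast after risk-changing rewards.

    For each neuron, trials N whose preceding trial N-1 was rewarded are
    split by the sign of the risk change ``risk[N] - risk[N-1]`` (using that
    neuron's relevant risk variable, a row of ``risk_matrix``).  Within each
    split the neuron's mean (sign-corrected, control-z-scored) activity on
    trials N is paired with its mean on trials N-1, and a Wilcoxon
    signed-rank test is run across neurons.  Risk-coding populations show
    increased activity when the reward increased reward variance and
    decreased activity when it decreased variance.
    """
    z = _control_zscores(counts, epoch, control)
    n_neurons, T = z.shape
    if signs is None:
        signs = np.ones(n_neurons)
    rew_prev = np.concatenate(([0], np.asarray(rewarded)[:-1])).astype(bool)
    out = {}
    for label, direction in (("increase", 1), ("decrease", -1)):
        cur, prev, n_trials = [], [], []
        for i in range(n_neurons):
            r = risk_matrix[i]
            dr = np.concatenate(([np.nan], np.diff(r)))
            m = rew_prev & valid & np.roll(valid, 1) & (direction * dr > 0)
            m[0] = False
            idx = np.flatnonzero(m)
            if len(idx) < 2:
                continue
            cur.append(signs[i] * z[i, idx].mean())
            prev.append(signs[i] * z[i, idx - 1].mean())
            n_trials.append(len(idx))
        cur, prev = np.array(cur), np.array(prev)
        if len(cur) < 5 or np.all(cur == prev):
            out[label] = {"n_neurons": len(cur), "p": np.nan,
                          "mean_N": np.nan, "mean_Nm1": np.nan,
                          "flagged": True}
            continue
        stat, p = stats.wilcoxon(cur, prev)
        out[label] = {"n_neurons": len(cur), "p": float(p),
                      "mean_N": float(cur.mean()),
                      "mean_Nm1": float(prev.mean()),
                      "direction": float(np.sign(cur.mean() - prev.mean())),
                      "flagged": False}
    return out


# ---------------------------------------------------------------------------
# non-stationarity controls
# ---------------------------------------------------------------------------

def nonstationarity_controls(reg: ResponseRegression, neuron: str | int,
                             epoch: str) -> dict[str, ResponseFit]:
    """Two controls against slow drifts for one response.

    ``'ar'``: the base model augmented with a first-order autoregressive term
    (previous trial's rate in the same epoch; first trial dropped).
    ``'control_subtracted'``: the control-period rate of the same trial is
    subtracted from the response before regression (skipped for the control
    epoch itself).
    """
    ni = (neuron if isinstance(neuron, int)
          else reg.counts.neuron_ids.index(neuron))
    ei = reg.counts.epoch_index(epoch)
    ci = reg.counts.epoch_index("Pre-fix")
    y = reg._y(ni, ei)
    nid = reg.counts.neuron_ids[ni]
    out = {}

    Xa = reg.X.copy()
    Xa["ar"] = np.concatenate(([np.nan], y[:-1]))
    keep = ~Xa["ar"].isna()
    out["ar"] = _fit_frame(y[keep.to_numpy()], Xa.loc[keep].reset_index(drop=True),
                           nid, epoch, reg.model)

    if ei != ci:
        ctrl = reg.counts.counts[ni, reg.valid, ci] / EPOCH_DURATION_S
        out["control_subtracted"] = _fit_frame(y - ctrl, reg.X, nid, epoch,
                                               reg.model)
    return out


# ---------------------------------------------------------------------------
# joint-coding statistics
# ---------------------------------------------------------------------------

def joint_coding_stats(coding: pd.DataFrame,
                       coefficients: pd.DataFrame | None = None) -> dict:
    """Pairwise joint-coding statistics across neurons.

    ``coding`` is a boolean neurons x variables table.  For each variable
    pair: a chi-square independence test of joint coding against the product
    of marginals (exact Fisher fallback, flagged, when an expected cell is
    below 5), and a z-test for dependent proportions comparing joint vs pure
    coding.  When ``coefficients`` (same shape, signed betas) is given, the
    cross-neuron regression between the coefficient pairs of jointly coding
    neurons is added.
    """
    variables = list(coding.columns)
    pairs = []
    for i, v1 in enumerate(variables):
        for v2 in variables[i + 1:]:
            a = coding[v1].to_numpy(dtype=bool)
            b = coding[v2].to_numpy(dtype=bool)
            table = np.array([[np.sum(a & b), np.sum(a & ~b)],
                              [np.sum(~a & b), np.sum(~a & ~b)]])
            expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
            fallback = bool((expected < 5).any())
            if fallback:
                _, p = stats.fisher_exact(table)
                chi2 = np.nan
            else:
                chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            zj, pj = dependent_proportions_ztest(a & b, a ^ b)
            row = {"var1": v1, "var2": v2, "n_joint": int(np.sum(a & b)),
                   "chi2": chi2, "p_independence": float(p),
                   "exact_fallback": fallback,
                   "z_joint_vs_pure": zj, "p_joint_vs_pure": pj}
            if coefficients is not None:
                m = a & b
                if m.sum() >= 3:
                    x = coefficients[v1].to_numpy()[m]
                    yv = coefficients[v2].to_numpy()[m]
                    res = sm.OLS(yv, sm.add_constant(x)).fit()
                    row["coef_slope"] = float(res.params[1])
                    row["coef_slope_p"] = float(res.pvalues[1])
                else:
                    row["coef_slope"] = np.nan
                    row["coef_slope_p"] = np.nan
            pairs.append(row)
    return {"pairs": pd.DataFrame(pairs)}
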