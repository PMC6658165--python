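"""Pseudo-population decoding of risk variables from spike counts.

Trials are split into terciles of a grouping variable (e.g. subjective object
risk) and a linear support-vector machine (or 1-nearest-neighbor) classifier
is trained to separate low- from high-tercile population activity vectors,
with leave-one-out cross-validation.  Because neurons are treated as
independently recorded, trials are randomly matched across neurons within
each group, and the whole procedure is repeated over matching iterations; a
group-label shuffle provides the chance distribution (50% for two balanced
groups).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .neurons import EpochCounts

__all__ = [
    "control_zscores",
    "tercile_groups",
    "PseudoPopulation",
    "build_pseudopopulation",
    "DecodingResult",
    "decode",
    "null_accuracies",
    "decoding_curve",
    "accuracy_vs_sensitivity",
    "control_decoding",
]

MIN_TRIALS_PER_GROUP = 8


def control_zscores(counts: EpochCounts, epoch: str,
                    control: str = "Pre-fix") -> np.ndarray:
    """Trial-by-trial rates z-normalized against the control period, per neuron."""
    ei = counts.epoch_index(epoch)
    ci = counts.epoch_index(control)
    act = counts.counts[:, :, ei].astype(float)
    mu = counts.counts[:, :, ci].mean(axis=1, keepdims=True)
    sd = counts.counts[:, :, ci].std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (act - mu) / sd


def tercile_groups(values: np.ndarray, valid: np.ndarray | None = None):
    """Rank-based low/high tercile trial indices (stable under ties).

    Returns (low_idx, high_idx); the middle tercile is discarded.
    """
    values = np.asarray(values, dtype=float)
    idx = np.arange(len(values))
    if valid is not None:
        idx = idx[np.asarray(valid, dtype=bool)]
    order = idx[np.argsort(values[idx], kind="stable")]
    n = len(order) // 3
    if n == 0:
        raise ValueError("too few trials for a tercile split")
    return order[:n], order[-n:]


@dataclass
class PseudoPopulation:
    """Two group-labelled (trials x neurons) matrices of z-scored activity."""

    low: np.ndarray
    high: np.ndarray
    neuron_ids: list
    matching_iteration: int = 0

    def xy(self):
        X = np.vstack([self.low, self.high])
        y = np.concatenate([np.zeros(len(self.low)), np.ones(len(self.high))])
        return X, y


def build_pseudopopulation(z: np.ndarray, grouping: np.ndarray,
                           rng: np.random.Generator,
                           valid: np.ndarray | None = None,
                           min_trials: int = MIN_TRIALS_PER_GROUP,
                           max_per_group: int | None = None,
                           neuron_ids: list | None = None,
                           matching_iteration: int = 0) -> PseudoPopulation:
    """Random within-group trial matching into low/high tercile matrices.

    ``z`` is (neurons x trials) z-scored activity; ``grouping`` is either one
    per-trial variable (shared by all neurons) or a (neurons x trials) matrix
    (each neuron grouped by its own variable, e.g. risk of object A for one
    copy and object B for the other).  Neurons with fewer than ``min_trials``
    per group are excluded; all included neurons are down-sampled without
    replacement to the common minimum group size.
    """
    z = np.asarray(z, dtype=float)
    n_neurons, T = z.shape
    grouping = np.asarray(grouping, dtype=float)
    if grouping.ndim == 1:
        grouping = np.tile(grouping, (n_neurons, 1))
    ids = neuron_ids if neuron_ids is not None else list(range(n_neurons))

    groups = []
    keep = []
    for i in range(n_neurons):
        lo, hi = tercile_groups(grouping[i], valid)
        if len(lo) >= min_trials and len(hi) >= min_trials:
            groups.append((lo, hi))
            keep.append(i)
    if not keep:
        raise ValueError("no neuron satisfies the minimum trials per group")
    m = min(min(len(lo), len(hi)) for lo, hi in groups)
    if max_per_group is not None:
        m = min(m, max_per_group)
    low = np.empty((m, len(keep)))
    high = np.empty((m, len(keep)))
    for j, (i, (lo, hi)) in enumerate(zip(keep, groups)):
        low[:, j] = z[i, rng.choice(lo, size=m, replace=False)]
        high[:, j] = z[i, rng.choice(hi, size=m, replace=False)]
    return PseudoPopulation(low=low, high=high,
                            neuron_ids=[ids[i] for i in keep],
                            matching_iteration=matching_iteration)


def _classifier(name: str):
    if name == "svm":
        return SVC(kernel="linear", C=1.0)
    if name == "nn":
        return KNeighborsClassifier(n_neighbors=1)
    raise ValueError(f"unknown classifier {name!r}")


def _loo_accuracy(X: np.ndarray, y: np.ndarray, classifier: str,
                  rng: np.random.Generator) -> float:
    """Leave-one-out cross-validated percent correct with balanced training.

    Holding out one trial from a balanced two-class set leaves the held-out
    class under-represented in training, which biases null accuracy below
    chance; one randomly chosen opposite-class trial is therefore also
    dropped from each training fold so the null distribution is centred on
    50%.
    """
    n = len(y)
    correct = 0
    skipped = 0
    idx = np.arange(n)
    for i in range(n):
        other = idx[(y != y[i]) & (idx != i)]
        if len(other) == 0 or np.sum((y == y[i]) & (idx != i)) == 0:
            skipped += 1
            continue
        drop = rng.choice(other)
        mask = (idx != i) & (idx != drop)
        clf = _classifier(classifier)
        clf.fit(X[mask], y[mask])
        correct += int(clf.predict(X[i][None, :])[0] == y[i])
    tested = n - skipped
    return 100.0 * correct / tested if tested else np.nan


@dataclass
class DecodingResult:
    """Decoding accuracy over matching iterations, with optional null."""

    accuracies: np.ndarray
    classifier: str
    n_neurons: int
    group_size: int
    variable: str = ""
    epoch: str = ""
    null: np.ndarray | None = None

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sem(self) -> float:
        if len(self.accuracies) < 2:
            return np.nan
        return float(np.std(self.accuracies, ddof=1)
                     / np.sqrt(len(self.accuracies)))

    def p_vs_null(self) -> float:
        """Rank-sum test of real vs shuffled accuracies."""
        if self.null is None:
            raise ValueError("no null distribution attached")
        return float(stats.ranksums(self.accuracies, self.null).pvalue)

    def summary(self) -> str:
        s = (f"Decoding [{self.classifier}] {self.variable} {self.epoch}: "
             f"{self.accuracy:.1f}% +/- {self.sem:.1f} "
             f"({self.n_neurons} neurons, {self.group_size}/group)")
        if self.null is not None:
            s += f"; null {np.mean(self.null):.1f}%, p={self.p_vs_null():.2g}"
        return s


def decode(z: np.ndarray, grouping: np.ndarray, rng: np.random.Generator,
           classifier: str = "svm", n_iterations: int = 30,
           valid: np.ndarray | None = None,
           min_trials: int = MIN_TRIALS_PER_GROUP,
           max_per_group: int | None = None,
           n_null: int = 0, variable: str = "",
           epoch: str = "") -> DecodingResult:
    """Tercile decoding accuracy over random trial-matching iterations.

    With ``n_null > 0`` a group-label-shuffled null distribution is attached
    (labels permuted without replacement within freshly matched matrices).
    """
    accs = []
    pop = None
    for it in range(n_iterations):
        pop = build_pseudopopulation(z, grouping, rng, valid, min_trials,
                                     max_per_group, matching_iteration=it)
        X, y = pop.xy()
        accs.append(_loo_accuracy(X, y, classifier, rng))
    null = None
    if n_null > 0:
        null = np.empty(n_null)
        pop = build_pseudopopulation(z, grouping, rng, valid, min_trials,
                                     max_per_group)
        X, y = pop.xy()
        for s in range(n_null):
            null[s] = _loo_accuracy(X, rng.permutation(y), classifier, rng)
    return DecodingResult(accuracies=np.asarray(accs), classifier=classifier,
                          n_neurons=len(pop.neuron_ids),
                          group_size=len(pop.low), null=null,
                          variable=variable, epoch=epoch)


def null_accuracies(z: np.ndarray, grouping: np.ndarray,
                    rng: np.random.Generator, classifier: str = "svm",
                    n_shuffles: int = 500, **kwargs) -> np.ndarray:
    """Group-label-shuffled decoding accuracies (chance distribution)."""
    pop = build_pseudopopulation(z, grouping, rng,
                                 kwargs.get("valid"),
                                 kwargs.get("min_trials", MIN_TRIALS_PER_GROUP),
                                 kwargs.get("max_per_group"))
    X, y = pop.xy()
    out = np.empty(n_shuffles)
    for s in range(n_shuffles):
        out[s] = _loo_accuracy(X, rng.permutation(y), classifier, rng)
    return out


def decoding_curve(z: np.ndarray, grouping: np.ndarray, sizes: list[int],
                   rng: np.random.Generator, classifier: str = "svm",
                   n_draws: int = 10, n_iterations: int = 5,
                   valid: np.ndarray | None = None,
                   max_per_group: int | None = None) -> pd.DataFrame:
    """Decoding accuracy as a function of population size.

    For each size, ``n_draws`` random neuron subsets are decoded; returns a
    table with mean and SE per size plus a Spearman trend test across the
    per-draw accuracies.
    """
    n_neurons = z.shape[0]
    rows = []
    all_sizes, all_accs = [], []
    for size in sizes:
        if size > n_neurons:
            raise ValueError(f"requested size {size} exceeds population "
                             f"{n_neurons}")
        accs = []
        for _ in range(n_draws):
            sel = rng.choice(n_neurons, size=size, replace=False)
            g = grouping if np.asarray(grouping).ndim == 1 else grouping[sel]
            res = decode(z[sel], g, rng, classifier, n_iterations,
                         valid=valid, max_per_group=max_per_group)
            accs.append(res.accuracy)
        rows.append({"size": size, "accuracy": float(np.mean(accs)),
                     "sem": float(np.std(accs, ddof=1) / np.sqrt(len(accs)))})
        all_sizes.extend([size] * len(accs))
        all_accs.extend(accs)
    table = pd.DataFrame(rows)
    rho, p = stats.spearmanr(all_sizes, all_accs)
    table.attrs["spearman_rho"] = float(rho)
    table.attrs["spearman_p"] = float(p)
    return table


def accuracy_vs_sensitivity(z: np.ndarray, grouping: np.ndarray,
                            betas: np.ndarray, rng: np.random.Generator,
                            n_subsets: int = 200, subset_size: int = 20,
                            classifier: str = "svm", n_iterations: int = 3,
                            valid: np.ndarray | None = None,
                            max_per_group: int | None = None) -> dict:
    """Regression of subset decoding accuracy on mean absolute risk beta.

    Draws random ``subset_size``-neuron subsets, decodes each, and regresses
    accuracy on the subset's mean |beta| (single-neuron risk sensitivity).
    """
    import statsmodels.api as sm
    n_neurons = z.shape[0]
    xs, ys = [], []
    for _ in range(n_subsets):
        sel = rng.choice(n_neurons, size=subset_size, replace=False)
        g = grouping if np.asarray(grouping).ndim == 1 else grouping[sel]
        res = decode(z[sel], g, rng, classifier, n_iterations, valid=valid,
                     max_per_group=max_per_group)
        xs.append(float(np.mean(np.abs(betas[sel]))))
        ys.append(res.accuracy)
    fit = sm.OLS(ys, sm.add_constant(np.asarray(xs))).fit()
    return {"slope": float(fit.params[1]), "p": float(fit.pvalues[1]),
            "r2": float(fit.rsquared),
            "subsets": pd.DataFrame({"mean_abs_beta": xs, "accuracy": ys})}


def control_decoding(z: np.ndarray, grouping: np.ndarray,
                     control_values: np.ndarray, rng: np.random.Generator,
                     classifier: str = "svm", n_iterations: int = 10,
                     valid: np.ndarray | None = None,
                     min_trials: int = MIN_TRIALS_PER_GROUP,
                     max_per_group: int | None = None) -> dict:
    """Decoding within trial subsets holding a control variable constant.

    Runs the tercile decoding separately at each level of
    ``control_values``; levels with too few trials are skipped (logged in
    the output).
    """
    control_values = np.asarray(control_values)
    if valid is None:
        valid = np.ones(z.shape[1], dtype=bool)
    out, skipped = {}, []
    for level in np.unique(control_values[valid]):
        m = valid & (control_values == level)
        if m.sum() < 3 * min_trials:
            skipped.append(level)
            continue
        try:
            out[level] = decode(z, grouping, rng, classifier, n_iterations,
                                valid=m, min_trials=min_trials,
                                max_per_group=max_per_group)
        except ValueError:
            skipped.append(level)
    return {"by_level": out, "skipped_levels": skipped}
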