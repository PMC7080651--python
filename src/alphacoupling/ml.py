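"""Nested cross-validated SVM protocol with exhaustive feature selection.

Implements the evaluation protocol around an RBF-kernel support vector
machine: feature subsets are enumerated and (C, g) hyperparameters grid
searched *inside* each outer training fold of a stratified 10-fold cross
validation, the winning combination is refit on the outer training set and
scored on the held-out fold, and the whole procedure is repeated (default
100 times) to yield percentile confidence intervals.  Min–max rescaling to
[0, 1] is fitted strictly on outer-training rows; a deliberate leakage
variant (rescaling fitted on all rows before the split) is available behind
a flag so its optimistic bias can be demonstrated.

The SVM optimizer itself is scikit-learn's; the protocol is what is
implemented here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC, SVR

#: Canonical feature ordering: 6 behavioral + 9 electrophysiological.
BEHAVIORAL_FEATURES = (
    "ER_congruent", "ER_incongruent", "RT_congruent", "RT_incongruent",
    "flankerER", "flankerRT",
)
EEG_FEATURES = (
    "alpha_congruent_fast", "alpha_congruent_slow",
    "alpha_incongruent_fast", "alpha_incongruent_slow",
    "alpha_grandmean", "alphadiff_congruent", "alphadiff_incongruent",
    "z_congruent", "z_incongruent",
)
ALL_FEATURES = BEHAVIORAL_FEATURES + EEG_FEATURES

#: Standard RBF search lattice: C = 2^-5 … 2^15, g = 2^-15 … 2^3, octave steps.
DEFAULT_C_GRID = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_G_GRID = tuple(2.0**e for e in range(-15, 4, 2))


class Rescaler01:
    """Per-feature min–max map to [0, 1], fitted on a designated row subset.

    Transformed values outside the fitted range extrapolate beyond [0, 1]
    (no clipping).  A constant feature in the fit rows is an error.
    """

    def fit(self, X: np.ndarray) -> "Rescaler01":
        X = np.asarray(X, dtype=float)
        self.min_ = X.min(axis=0)
        rng = X.max(axis=0) - self.min_
        if np.any(rng == 0):
            bad = np.where(rng == 0)[0].tolist()
            raise ValueError(f"constant feature(s) in fit rows: columns {bad}")
        self.range_ = rng
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.min_) / self.range_


def rescale01(
    X: np.ndarray | pd.DataFrame, fit_rows: np.ndarray | None = None
) -> tuple[np.ndarray, Rescaler01]:
    """Rescale all rows using min/max from ``fit_rows`` (default: all rows)."""
    cols = None
    if isinstance(X, pd.DataFrame):
        cols = X.columns
        X = X.to_numpy(dtype=float)
    fit_rows = np.arange(len(X)) if fit_rows is None else np.asarray(fit_rows)
    sc = Rescaler01().fit(X[fit_rows])
    out = sc.transform(X)
    if cols is not None:
        out = pd.DataFrame(out, columns=cols)
    return out, sc


def candidate_subsets(
    n_features: int, max_size: int | None = None
) -> list[tuple[int, ...]]:
    """All non-empty feature-index subsets up to ``max_size`` (enumeration
    order: by size, then lexicographic)."""
    if n_features < 1:
        raise ValueError("need at least one feature")
    max_size = n_features if max_size is None else min(max_size, n_features)
    subsets = []
    for r in range(1, max_size + 1):
        subsets.extend(itertools.combinations(range(n_features), r))
    return subsets


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> dict:
    """Rates from a 2×2 confusion matrix.

    Undefined ratios (zero denominator) are reported as NaN, never as 0.
    """
    if min(tp, fp, fn, tn) < 0 or tp + fp + fn + tn == 0:
        raise ValueError("counts must be nonnegative with a positive total")

    def _ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    return {
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "ppv": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
        "accuracy": (tp + tn) / (tp + fp + fn + tn),
    }


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: probability a random positive outranks a random
    negative, ties counted one half."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("need exactly two classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class CVReport:
    """Per-repetition and aggregate metrics of a nested-CV run."""

    task: str
    per_rep: pd.DataFrame
    summary: pd.DataFrame  # index metric; columns mean, ci_lo, ci_hi
    selections: list[dict] = field(default_factory=list)
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "per_rep": self.per_rep.to_dict(orient="list"),
            "summary": self.summary.to_dict(orient="index"),
            "selections": self.selections,
            "seed": self.seed,
        }


def _summarize(per_rep: pd.DataFrame) -> pd.DataFrame:
    rows = {}
    for col in per_rep.columns:
        v = per_rep[col].to_numpy(dtype=float)
        rows[col] = {
            "mean": float(np.nanmean(v)),
            "ci_lo": float(np.nanpercentile(v, 2.5)),
            "ci_hi": float(np.nanpercentile(v, 97.5)),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def _grid_pairs(c_grid, g_grid) -> list[tuple[float, float]]:
    return [(float(c), float(g)) for c in c_grid for g in g_grid]


def nested_cv_classify(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    c_grid=DEFAULT_C_GRID,
    g_grid=DEFAULT_G_GRID,
    subsets: list[tuple[int, ...]] | None = None,
    max_subset_size: int | None = 2,
    k: int = 10,
    reps: int = 100,
    seed: int = 0,
    leak_rescale: bool = False,
) -> CVReport:
    """Nested k-fold cross-validated RBF-SVM classification.

    Per repetition: stratified outer k-fold; within each outer training set
    an inner stratified k-fold scores every (feature subset, C, g)
    combination by mean accuracy; the winner (ties → smaller subset, then
    enumeration order, then smaller C, then smaller g) is refit on the full
    outer training set and evaluated on the held-out fold.  Outer-fold
    predictions are pooled per repetition into confusion metrics and AUC;
    aggregates are means with 2.5/97.5 percentile CIs over repetitions.

    ``y`` may be any two-label vector; the lexicographically larger label is
    the positive class.  With ``leak_rescale=True`` the 0–1 rescaling is
    fitted on *all* rows before splitting (the leaky variant).
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    pos = classes[-1]
    ybin = (y == pos).astype(int)
    counts = np.bincount(ybin)
    if counts.min() < k:
        raise ValueError(f"need >= k={k} subjects per class, got {counts.tolist()}")
    if not c_grid or not g_grid:
        raise ValueError("empty hyperparameter grid")
    if subsets is None:
        subsets = candidate_subsets(X.shape[1], max_subset_size)
    if not subsets:
        raise ValueError("empty subset iterator")
    grid = _grid_pairs(c_grid, g_grid)

    rep_rows = []
    selections = []
    for rep in range(reps):
        rep_seed = seed + rep
        outer = StratifiedKFold(n_splits=k, shuffle=True, random_state=rep_seed)
        pooled_pred = np.empty(len(y), dtype=int)
        pooled_score = np.empty(len(y), dtype=float)
        for fold_i, (tr, te) in enumerate(outer.split(X, ybin)):
            if leak_rescale:
                sc = Rescaler01().fit(X)
            else:
                sc = Rescaler01().fit(X[tr])
            Xs = sc.transform(X)
            best = None
            # inner fold count cannot exceed the smallest class in the
            # outer-training set (only binds for very small cohorts)
            k_inner = min(k, int(np.bincount(ybin[tr]).min()))
            inner = StratifiedKFold(
                n_splits=k_inner, shuffle=True, random_state=rep_seed
            )
            inner_folds = list(inner.split(Xs[tr], ybin[tr]))
            for s_i, sub in enumerate(subsets):
                Xsub = Xs[tr][:, sub]
                for C, g in grid:
                    correct = 0
                    total = 0
                    for itr, ite in inner_folds:
                        clf = SVC(C=C, gamma=g, kernel="rbf")
                        clf.fit(Xsub[itr], ybin[tr][itr])
                        correct += int((clf.predict(Xsub[ite]) == ybin[tr][ite]).sum())
                        total += len(ite)
                    acc = correct / total
                    key = (-acc, len(sub), s_i, C, g)
                    if best is None or key < best[0]:
                        best = (key, sub, C, g)
            _, sub, C, g = best
            clf = SVC(C=C, gamma=g, kernel="rbf")
            clf.fit(Xs[tr][:, sub], ybin[tr])
            pooled_pred[te] = clf.predict(Xs[te][:, sub])
            pooled_score[te] = clf.decision_function(Xs[te][:, sub])
            selections.append(
                {"rep": rep, "fold": fold_i, "subset": list(sub), "C": C, "g": g}
            )
        tp = int(((pooled_pred == 1) & (ybin == 1)).sum())
        fp = int(((pooled_pred == 1) & (ybin == 0)).sum())
        fn = int(((pooled_pred == 0) & (ybin == 1)).sum())
        tn = int(((pooled_pred == 0) & (ybin == 0)).sum())
        metrics = confusion_metrics(tp, fp, fn, tn)
        metrics["auc"] = roc_auc(pooled_score, ybin)
        metrics.update({"tp": tp, "fp": fp, "fn": fn, "tn": tn})
        rep_rows.append(metrics)

    per_rep = pd.DataFrame(rep_rows)
    return CVReport(
        task="classification",
        per_rep=per_rep,
        summary=_summarize(per_rep),
        selections=selections,
        seed=seed,
    )


def nested_cv_regress(
    X: np.ndarray | pd.DataFrame,
    target: np.ndarray,
    c_grid=DEFAULT_C_GRID,
    g_grid=DEFAULT_G_GRID,
    subsets: list[tuple[int, ...]] | None = None,
    max_subset_size: int | None = 2,
    k: int = 10,
    reps: int = 100,
    seed: int = 0,
    leak_rescale: bool = False,
) -> CVReport:
    """Nested k-fold cross-validated RBF-SVM regression.

    Same nesting as classification with plain (unstratified) k-folds and
    mean squared error as the inner selection criterion.  Targets are
    rescaled to [0, 1] alongside the features (fit on outer-training rows),
    so MSE is on the rescaled scale.  Two R² conventions are reported over
    the pooled out-of-fold predictions: ``r2`` — squared Pearson correlation
    between predicted and observed (primary) — and ``r2_ss`` = 1 − SSE/SST,
    which can be negative.
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    target = np.asarray(target, dtype=float)
    if np.ptp(target) == 0:
        raise ValueError("constant target")
    if subsets is None:
        subsets = candidate_subsets(X.shape[1], max_subset_size)
    if not subsets:
        raise ValueError("empty subset iterator")
    grid = _grid_pairs(c_grid, g_grid)

    rep_rows = []
    selections = []
    for rep in range(reps):
        rep_seed = seed + rep
        outer = KFold(n_splits=k, shuffle=True, random_state=rep_seed)
        pooled_pred = np.empty(len(target))
        pooled_obs = np.empty(len(target))
        for fold_i, (tr, te) in enumerate(outer.split(X)):
            fit_rows = np.arange(len(X)) if leak_rescale else tr
            sc = Rescaler01().fit(X[fit_rows])
            Xs = sc.transform(X)
            t_min = target[fit_rows].min()
            t_rng = np.ptp(target[fit_rows])
            if t_rng == 0:
                raise ValueError("constant target in training rows")
            ts = (target - t_min) / t_rng
            best = None
            k_inner = min(k, len(tr))
            inner = KFold(n_splits=k_inner, shuffle=True, random_state=rep_seed)
            inner_folds = list(inner.split(Xs[tr]))
            for s_i, sub in enumerate(subsets):
                Xsub = Xs[tr][:, sub]
                tsub = ts[tr]
                for C, g in grid:
                    sse = 0.0
                    total = 0
                    for itr, ite in inner_folds:
                        reg = SVR(C=C, gamma=g, kernel="rbf")
                        reg.fit(Xsub[itr], tsub[itr])
                        err = reg.predict(Xsub[ite]) - tsub[ite]
                        sse += float(err @ err)
                        total += len(ite)
                    mse = sse / total
                    key = (mse, len(sub), s_i, C, g)
                    if best is None or key < best[0]:
                        best = (key, sub, C, g)
            _, sub, C, g = best
            reg = SVR(C=C, gamma=g, kernel="rbf")
            reg.fit(Xs[tr][:, sub], ts[tr])
            pooled_pred[te] = reg.predict(Xs[te][:, sub])
            pooled_obs[te] = ts[te]
            selections.append(
                {"rep": rep, "fold": fold_i, "subset": list(sub), "C": C, "g": g}
            )
        resid = pooled_pred - pooled_obs
        mse = float(resid @ resid / len(resid))
        sst = float(np.sum((pooled_obs - pooled_obs.mean()) ** 2))
        r2_ss = 1.0 - float(resid @ resid) / sst if sst > 0 else float("nan")
        if np.ptp(pooled_pred) == 0:
            r2 = float("nan")
        else:
            r2 = float(np.corrcoef(pooled_pred, pooled_obs)[0, 1] ** 2)
        rep_rows.append({"r2": r2, "r2_ss": r2_ss, "mse": mse})

    per_rep = pd.DataFrame(rep_rows)
    return CVReport(
        task="regression",
        per_rep=per_rep,
        summary=_summarize(per_rep),
        selections=selections,
        seed=seed,
    )
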