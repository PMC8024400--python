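"""Individual differences: performance index, classifiability, and the
connectome predictor.

The behavioural performance index (PI) is a subject's score on the first
unrotated principal component of the z-scored 12 task scores (sign fixed so
the mean task loading is positive).  Per-subject classifiability is the
fraction of a subject's task blocks (36 at study scale) correctly labelled
by models naive to that subject.  Their association uses a right-tailed
Pearson test with BH-FDR across the declared family of models.  Finally an
ensemble of boosted least-squares regression trees predicts the PI from the
28 within/between-network connectivity features, with a leave-one-subject-
out grid search over (max branch-node splits, number of trees).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor
from statsmodels.stats.multitest import multipletests

from .similarity import _one_tailed_pearson

__all__ = [
    "PerformanceIndex",
    "SubjectAccuracy",
    "TreeEnsembleSpec",
    "TreeEval",
    "performance_index",
    "subject_classifiability",
    "accuracy_pi_association",
    "boosted_tree_regression",
]


# --------------------------------------------------------------------------
# Performance index
# --------------------------------------------------------------------------

@dataclass
class PerformanceIndex:
    pi: np.ndarray                 # zero mean, unit variance, subject order
    loadings: np.ndarray           # task -> PC1 weight
    explained_variance: float
    subjects: np.ndarray


def performance_index(scores: pd.DataFrame | np.ndarray) -> PerformanceIndex:
    """First unrotated principal component of the subject x task score table.

    Columns are z-scored; the PC1 sign is fixed so the mean task loading is
    non-negative; PI scores are returned z-scored across subjects.
    """
    if isinstance(scores, pd.DataFrame):
        subjects = scores.index.to_numpy()
        M = scores.to_numpy(dtype=float)
    else:
        M = np.asarray(scores, dtype=float)
        subjects = np.arange(M.shape[0])
    if M.shape[0] < 3:
        raise ValueError("need >= 3 subjects")
    if np.any(~np.isfinite(M)):
        warnings.warn("missing scores mean-imputed per task", stacklevel=2)
        col_mean = np.nanmean(M, axis=0)
        M = np.where(np.isfinite(M), M, col_mean[None, :])
    sd = M.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("rank-0 score table")
    Z = (M - M.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    load = Vt[0]
    if load.mean() < 0:
        load = -load
        U[:, 0] = -U[:, 0]
    pc1 = U[:, 0] * S[0]
    pc1 = (pc1 - pc1.mean()) / pc1.std()
    ev = float(S[0] ** 2 / np.sum(S ** 2))
    return PerformanceIndex(pi=pc1, loadings=load, explained_variance=ev,
                            subjects=subjects)


# --------------------------------------------------------------------------
# Subject classifiability
# --------------------------------------------------------------------------

@dataclass
class SubjectAccuracy:
    subject: object
    correct: int
    total: int
    accuracy: float
    outlier_flag: bool


def subject_classifiability(event_subjects: np.ndarray, event_tested: np.ndarray,
                            event_correct: np.ndarray, n_classes: int = 12
                            ) -> list[SubjectAccuracy]:
    """Per-subject block classification accuracy from held-out predictions.

    Every event must have been scored by models naive to its subject (the
    repeated held-out or leave-one-subject-out protocols guarantee this);
    with repeated splits each event's correctness is the fraction of test
    appearances it was labelled correctly.  A subject is outlier-flagged
    when accuracy < chance + 2/total or > 3 SD below the cohort mean.
    """
    event_subjects = np.asarray(event_subjects)
    subjects = np.unique(event_subjects)
    accs = []
    for s in subjects:
        sel = event_subjects == s
        if np.any(event_tested[sel] == 0):
            raise ValueError(f"subject {s} has events never scored held-out")
        frac = event_correct[sel] / event_tested[sel]
        total = int(sel.sum())
        accs.append((s, float(frac.mean()), total))
    mean_acc = float(np.mean([a for _, a, _ in accs]))
    sd_acc = float(np.std([a for _, a, _ in accs]))
    out = []
    for s, acc, total in accs:
        low_abs = acc < 1.0 / n_classes + 2.0 / total
        low_rel = sd_acc > 0 and acc < mean_acc - 3.0 * sd_acc
        out.append(SubjectAccuracy(subject=s, correct=int(round(acc * total)),
                                   total=total, accuracy=acc,
                                   outlier_flag=bool(low_abs or low_rel)))
    return out


def accuracy_pi_association(acc_sets: dict[str, list[SubjectAccuracy]],
                            pi: PerformanceIndex, alpha: float = 0.05) -> pd.DataFrame:
    """Right-tailed Pearson r between accuracy and PI per model, BH-FDR family.

    ``acc_sets`` maps a model tag (metric/ROI-set) to its per-subject
    accuracies; outlier-flagged subjects are excluded per model.
    """
    rows = []
    pi_by_subject = dict(zip(pi.subjects, pi.pi))
    for name, accs in acc_sets.items():
        kept = [a for a in accs if not a.outlier_flag]
        if len(kept) < 10:
            raise ValueError(f"{name}: fewer than 10 non-outlier subjects")
        x = np.array([pi_by_subject[a.subject] for a in kept])
        y = np.array([a.accuracy for a in kept])
        r, p = _one_tailed_pearson(x, y, "right")
        rows.append({"model": name, "r": r, "p": p, "n": len(kept),
                     "n_excluded": len(accs) - len(kept)})
    df = pd.DataFrame(rows)
    _, p_fdr, _, _ = multipletests(df["p"], alpha=alpha, method="fdr_bh")
    df["p_fdr"] = p_fdr
    return df


# --------------------------------------------------------------------------
# Boosted regression trees
# --------------------------------------------------------------------------

@dataclass
class TreeEnsembleSpec:
    max_splits: int
    n_trees: int
    learn_rate: float = 1.0
    loss: str = "squared_error"

    def __post_init__(self) -> None:
        if self.max_splits < 1 or self.n_trees < 1:
            raise ValueError("max_splits and n_trees must be >= 1")
        if not 0 < self.learn_rate <= 1:
            raise ValueError("learn_rate must lie in (0, 1]")

    def make(self) -> GradientBoostingRegressor:
        # max_leaf_nodes = branch-node splits + 1
        return GradientBoostingRegressor(loss=self.loss, n_estimators=self.n_trees,
                                         learning_rate=self.learn_rate,
                                         max_leaf_nodes=self.max_splits + 1,
                                         max_depth=None, random_state=0)


@dataclass
class TreeEval:
    loo_predictions: np.ndarray
    mse: float
    r: float
    p: float
    importance: np.ndarray
    spec: TreeEnsembleSpec
    grid_mse: dict = field(default_factory=dict)


DEFAULT_GRID = {"max_splits": (1, 2, 3, 5), "n_trees": (3, 5, 10, 25)}


def _loo_mse(X: np.ndarray, y: np.ndarray, spec: TreeEnsembleSpec) -> tuple[float, np.ndarray]:
    preds = np.empty_like(y)
    for i in range(len(y)):
        mask = np.arange(len(y)) != i
        model = spec.make().fit(X[mask], y[mask])
        preds[i] = model.predict(X[i:i + 1])[0]
    return float(np.mean((preds - y) ** 2)), preds


def boosted_tree_regression(features: np.ndarray, pi: PerformanceIndex,
                            grid: dict | None = None,
                            learn_rate: float = 1.0) -> TreeEval:
    """LOO grid search + evaluation of a boosted least-squares tree ensemble.

    ``features`` is subjects x 28 network features aligned to ``pi``.  The
    grid over (max_splits, n_trees) is scored by leave-one-subject-out MSE;
    the selected spec's LOO predictions give the reported MSE and right-
    tailed Pearson r; split-gain importance comes from a full-sample fit of
    the selected spec (not cross-validated, for inspection only).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(pi.pi, dtype=float)
    if X.shape[0] != len(y):
        raise ValueError("features not aligned to performance index")
    if X.shape[0] < 10:
        raise ValueError("need >= 10 subjects")
    if y.std() == 0:
        raise ValueError("constant target")
    grid = dict(DEFAULT_GRID if grid is None else grid)
    combos = list(product(grid["max_splits"], grid["n_trees"]))
    if not combos:
        raise ValueError("empty grid")
    grid_mse = {}
    best_spec, best_mse, best_preds = None, np.inf, None
    for max_splits, n_trees in combos:
        spec = TreeEnsembleSpec(max_splits=max_splits, n_trees=n_trees,
                                learn_rate=learn_rate)
        mse, preds = _loo_mse(X, y, spec)
        grid_mse[(max_splits, n_trees)] = mse
        if mse < best_mse:
            best_spec, best_mse, best_preds = spec, mse, preds
    if np.std(best_preds) == 0:
        r, p = 0.0, 1.0
    else:
        r, p = _one_tailed_pearson(y, best_preds, "right")
    full = best_spec.make().fit(X, y)
    return TreeEval(loo_predictions=best_preds, mse=best_mse, r=r, p=p,
                    importance=full.feature_importances_, spec=best_spec,
                    grid_mse=grid_mse)
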