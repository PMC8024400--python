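"""Multi-way task-state classification with repeated held-out validation.

The 12-way problem is solved with an error-correcting output codes (ECOC)
reduction over linear support-vector machines — one-vs-all (12 learners) or
one-vs-one (66) — decoded by minimal aggregate hinge loss against the code
matrix, with no hyperparameter tuning (fixed C = 1, features z-scored on
training statistics).  Evaluation splits by subject (75% train / 25% test),
repeated to form performance distributions, with matched null models trained
on within-subject scrambled labels and empirical significance
p = (b + 1) / (m + 1).  Also provided: the two-stage stack over activation
and connectivity metrics, pairwise binary classification, meta-class
evaluation with class-size-preserving permutations, and sparse L1
connection selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from . import activation as _act
from . import connectivity as _conn
from .similarity import SimilarityMatrix, similarity_association_test

__all__ = [
    "FeatureTable",
    "ClassificationReport",
    "PermutationDistribution",
    "MetaClassScheme",
    "SparseWeightSummary",
    "EcocModel",
    "fit_ecoc",
    "f1_scores",
    "empirical_p",
    "repeated_heldout_eval",
    "stack_heldout_eval",
    "pairwise_binary_eval",
    "metaclass_eval",
    "sparse_connection_selection",
    "ba_feature_table",
    "dfc_feature_table",
]


# --------------------------------------------------------------------------
# Data structures
# --------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Events x features matrix with task labels and subject groups."""

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.groups = np.asarray(self.groups)
        if not (len(self.X) == len(self.y) == len(self.groups)):
            raise ValueError("X, y, groups must be aligned")

    @property
    def n_events(self) -> int:
        return len(self.y)

    def subset(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.X[idx], self.y[idx], self.groups[idx], dict(self.meta))


@dataclass
class ClassificationReport:
    classes: np.ndarray
    f1_minor: np.ndarray
    f1_macro: float
    confusion: np.ndarray          # rows = truth, cols = predicted
    per_event: np.ndarray          # predicted label per event


@dataclass
class PermutationDistribution:
    """True vs scrambled-label F1 distributions over m repetitions."""

    true_scores: np.ndarray
    null_scores: np.ndarray

    @property
    def m(self) -> int:
        return len(self.null_scores)

    @property
    def b(self) -> int:
        return int(np.sum(self.null_scores > float(np.mean(self.true_scores))))


def empirical_p(dist: PermutationDistribution) -> float:
    """Empirical probability p = (b + 1) / (m + 1)."""
    if dist.m < 1 or len(dist.true_scores) < 1:
        raise ValueError("empty distributions")
    return (dist.b + 1) / (dist.m + 1)


# --------------------------------------------------------------------------
# F1 scoring
# --------------------------------------------------------------------------

def f1_scores(pred: np.ndarray, truth: np.ndarray,
              classes: np.ndarray | None = None) -> ClassificationReport:
    """Per-class f1-minor = 2rp/(p+r) and their unweighted mean (F1-macro)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred/truth misaligned")
    if classes is None:
        classes = np.unique(truth)
    k = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(truth, pred):
        if p in index:
            confusion[index[t], index[p]] += 1
    f1 = np.zeros(k)
    for i in range(k):
        tp = confusion[i, i]
        fp = confusion[:, i].sum() - tp
        fn = confusion[i, :].sum() - tp
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1[i] = 2 * recall * precision / (precision + recall) if precision + recall else 0.0
    return ClassificationReport(classes=np.asarray(classes), f1_minor=f1,
                                f1_macro=float(f1.mean()), confusion=confusion,
                                per_event=pred)


# --------------------------------------------------------------------------
# ECOC model
# --------------------------------------------------------------------------

def _code_matrix(n_classes: int, scheme: str) -> np.ndarray:
    if scheme == "ova":
        code = -np.ones((n_classes, n_classes))
        np.fill_diagonal(code, 1.0)
        return code
    if scheme == "ovo":
        pairs = [(a, b) for a in range(n_classes) for b in range(a + 1, n_classes)]
        code = np.zeros((n_classes, len(pairs)))
        for l, (a, b) in enumerate(pairs):
            code[a, l] = 1.0
            code[b, l] = -1.0
        return code
    raise ValueError("scheme must be 'ova' or 'ovo'")


class EcocModel:
    """ECOC ensemble of linear SVMs with hinge-loss decoding.

    Features are z-scored on the training statistics; each code-matrix
    column trains one binary LinearSVC (C fixed, no tuning).  Prediction
    picks the class with minimal aggregate hinge loss against the code
    matrix, ties broken by lowest class index.  The signed decision values
    of the learners ("positive binary scores", PBS) are exposed for
    stacking.
    """

    def __init__(self, scheme: str = "ova", C: float = 1.0, max_iter: int = 5000):
        self.scheme = scheme
        self.C = C
        self.max_iter = max_iter

    def fit(self, X: np.ndarray, y: np.ndarray) -> "EcocModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need >= 2 classes present in training data")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 1e-12, sd, 1.0)
        Xs = (X - self.mean_) / self.scale_
        self.code_ = _code_matrix(len(self.classes_), self.scheme)
        yi = np.searchsorted(self.classes_, y)
        self.learners_ = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # liblinear convergence chatter
            for l in range(self.code_.shape[1]):
                col = self.code_[:, l]
                sel = col[yi] != 0
                target = np.sign(col[yi[sel]])
                clf = LinearSVC(C=self.C, max_iter=self.max_iter, random_state=0)
                clf.fit(Xs[sel], target)
                self.learners_.append(clf)
        return self

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Signed learner scores per event (events x learners); OVA = PBS."""
        Xs = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        return np.column_stack([clf.decision_function(Xs) for clf in self.learners_])

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_scores(X)
        code = self.code_
        weight = np.abs(code)
        # aggregate hinge loss of each class's codeword against learner scores
        margins = code[None, :, :] * scores[:, None, :]
        loss = (weight[None, :, :] * np.clip(1.0 - margins, 0.0, None)).sum(axis=2)
        loss = loss / weight.sum(axis=1)[None, :]
        best = np.argmin(loss, axis=1)  # argmin takes the first (lowest) index on ties
        return self.classes_[best]


def fit_ecoc(train: FeatureTable, scheme: str = "ova", C: float = 1.0) -> EcocModel:
    """Fit an ECOC model on a feature table (spec-level convenience)."""
    return EcocModel(scheme=scheme, C=C).fit(train.X, train.y)


# --------------------------------------------------------------------------
# Feature-table construction from a synthetic cohort
# --------------------------------------------------------------------------

def ba_feature_table(cohort) -> FeatureTable:
    """Per-event BOLD-activation features: one block-design GLM beta per ROI."""
    cfg = cohort.config
    rows, y, groups = [], [], []
    for s in range(cfg.n_subjects):
        for t in range(cfg.n_tasks):
            ev = cohort.run_events(s, t)
            design = _act.build_block_design(ev, cfg.tr_s, cfg.frames_per_run)
            ts = cohort.roi_timeseries[s, :, cohort.run_slice(t)]
            betas = _act.estimate_block_betas(ts, design)
            for _, rec in betas.sort_values("block").iterrows():
                rows.append(rec["beta"])
                y.append(t)
                groups.append(s)
    return FeatureTable(np.stack(rows), np.array(y), np.array(groups),
                        {"metric": "BA", "n_rois": cfg.n_rois})


def dfc_feature_table(cohort, baseline: str = "subject", **fir_kwargs) -> FeatureTable:
    """Per-event dFC features: task-minus-rest Fisher-z per ROI pair.

    ``baseline="subject"`` (default) pools rest frames across the subject's
    runs for the rest Fisher z — rest is a task-independent steady state and
    a single run's ~20 s rest windows give a very noisy baseline;
    ``baseline="run"`` uses each run's own rest frames.
    """
    if baseline not in ("subject", "run"):
        raise ValueError("baseline must be 'subject' or 'run'")
    cfg = cohort.config
    rows, y, groups = [], [], []
    for s in range(cfg.n_subjects):
        firs = []
        for t in range(cfg.n_tasks):
            ev = cohort.run_events(s, t)
            ts = cohort.roi_timeseries[s, :, cohort.run_slice(t)]
            firs.append(_conn.fir_regress(ts, ev, cfg.tr_s, **fir_kwargs))
        rest_z = _conn.pooled_rest_z(firs) if baseline == "subject" else None
        for t, fir in enumerate(firs):
            vecs, info = _conn.block_dfc(fir, rest_z=rest_z)
            order = np.argsort(info["block"].to_numpy())
            for i in order:
                rows.append(vecs[i])
                y.append(t)
                groups.append(s)
    return FeatureTable(np.stack(rows), np.array(y), np.array(groups),
                        {"metric": "dFC", "n_rois": cfg.n_rois, "baseline": baseline})


# --------------------------------------------------------------------------
# Repeated held-out protocol
# --------------------------------------------------------------------------

def _subject_split(subjects: np.ndarray, train_frac: float,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    subjects = np.array(sorted(subjects))
    perm = rng.permutation(subjects)
    n_test = max(1, int(round((1.0 - train_frac) * len(subjects))))
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def _scramble_within_subject(y: np.ndarray, groups: np.ndarray,
                             rng: np.random.Generator) -> np.ndarray:
    out = y.copy()
    for s in np.unique(groups):
        sel = np.where(groups == s)[0]
        out[sel] = y[sel][rng.permutation(len(sel))]
    return out


def _assert_no_leakage(train_groups: np.ndarray, test_groups: np.ndarray) -> None:
    if np.intersect1d(train_groups, test_groups).size:
        raise AssertionError("subject leakage between train and test")


def _group_kfold(subjects: np.ndarray, k: int,
                 rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray]]:
    subjects = np.array(sorted(subjects))
    perm = rng.permutation(subjects)
    folds = np.array_split(perm, k)
    return [(np.sort(np.concatenate(folds[:i] + folds[i + 1:])), np.sort(folds[i]))
            for i in range(k)]


@dataclass
class HeldOutResult:
    """Outcome of the repeated subject-level held-out protocol."""

    dist: PermutationDistribution
    cv_scores: np.ndarray
    reports: list
    event_tested: np.ndarray       # times each event landed in a test set
    event_correct: np.ndarray
    scheme: str

    @property
    def p(self) -> float:
        return empirical_p(self.dist)


def repeated_heldout_eval(data: FeatureTable, n_rep: int = 100,
                          train_frac: float = 0.75, seed: int = 0,
                          scheme: str = "ova", C: float = 1.0,
                          cv_folds: int = 5, with_cv: bool = True,
                          with_true: bool = True,
                          with_null: bool = True) -> HeldOutResult:
    """Repeated 75/25 subject-level held-out evaluation with matched nulls.

    Per repetition: a true model on the training subjects and a null model
    on within-subject scrambled training labels, both scored on the held-out
    subjects; optionally a ``cv_folds``-fold subject-grouped CV estimate
    inside the training set (reported separately — CV is optimistic relative
    to held-out).
    """
    subjects = np.unique(data.groups)
    if len(subjects) < 8:
        raise ValueError("need >= 8 subjects for the held-out protocol")
    rng = np.random.default_rng(seed)
    true_f1, null_f1, cv_f1, reports = [], [], [], []
    n_events = data.n_events
    tested = np.zeros(n_events, dtype=int)
    correct = np.zeros(n_events, dtype=int)
    for _ in range(n_rep):
        train_subj, test_subj = _subject_split(subjects, train_frac, rng)
        _assert_no_leakage(train_subj, test_subj)
        tr = np.isin(data.groups, train_subj)
        te = ~tr
        if with_true:
            model = EcocModel(scheme, C).fit(data.X[tr], data.y[tr])
            pred = model.predict(data.X[te])
            rep = f1_scores(pred, data.y[te], classes=np.unique(data.y))
            true_f1.append(rep.f1_macro)
            reports.append(rep)
            idx = np.where(te)[0]
            tested[idx] += 1
            correct[idx] += (pred == data.y[te]).astype(int)
        if with_null:
            y_null = _scramble_within_subject(data.y[tr], data.groups[tr], rng)
            null_model = EcocModel(scheme, C).fit(data.X[tr], y_null)
            null_rep = f1_scores(null_model.predict(data.X[te]), data.y[te],
                                 classes=np.unique(data.y))
            null_f1.append(null_rep.f1_macro)
        if with_cv and with_true:
            # event-level folds (not subject-grouped): the CV estimate is
            # expected to be optimistic relative to held-out subjects
            tr_idx = np.where(tr)[0]
            perm_events = rng.permutation(tr_idx)
            fold_scores = []
            for fold in np.array_split(perm_events, cv_folds):
                cv_tr = np.setdiff1d(tr_idx, fold)
                m = EcocModel(scheme, C).fit(data.X[cv_tr], data.y[cv_tr])
                fold_scores.append(
                    f1_scores(m.predict(data.X[fold]), data.y[fold],
                              classes=np.unique(data.y)).f1_macro)
            cv_f1.append(float(np.mean(fold_scores)))
    return HeldOutResult(
        dist=PermutationDistribution(np.asarray(true_f1), np.asarray(null_f1)),
        cv_scores=np.asarray(cv_f1), reports=reports,
        event_tested=tested, event_correct=correct, scheme=scheme)


# --------------------------------------------------------------------------
# Two-stage stack
# --------------------------------------------------------------------------

def _stage1_pbs(table: FeatureTable, tr: np.ndarray, te: np.ndarray,
                folds: list[tuple[np.ndarray, np.ndarray]], C: float
                ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Out-of-fold PBS for training events and per-fold PBS for test events."""
    n_classes = len(np.unique(table.y[tr]))
    oof = np.zeros((int(tr.sum()), n_classes))
    tr_idx = np.where(tr)[0]
    pos_in_train = {e: i for i, e in enumerate(tr_idx)}
    test_pbs = []
    for fold_tr_subj, fold_te_subj in folds:
        f_tr = np.isin(table.groups, fold_tr_subj)
        f_te = np.isin(table.groups, fold_te_subj) & tr
        model = EcocModel("ova", C).fit(table.X[f_tr], table.y[f_tr])
        scores = model.decision_scores(table.X[f_te])
        for row, e in zip(scores, np.where(f_te)[0]):
            oof[pos_in_train[e]] = row
        test_pbs.append(model.decision_scores(table.X[te]))
    return oof, test_pbs


def _mode_vote(votes: np.ndarray) -> np.ndarray:
    """Majority vote across rows of votes (models x events); ties -> lowest label."""
    out = np.empty(votes.shape[1], dtype=votes.dtype)
    for j in range(votes.shape[1]):
        vals, counts = np.unique(votes[:, j], return_counts=True)
        out[j] = vals[np.argmax(counts)]  # unique is sorted -> lowest label on ties
    return out


def stack_heldout_eval(tables: dict[str, FeatureTable], n_rep: int = 100,
                       train_frac: float = 0.75, seed: int = 0, C: float = 1.0,
                       cv_folds: int = 5, with_null: bool = False) -> HeldOutResult:
    """Repeated held-out evaluation of the two-stage stack model.

    Stage 1, per metric: an internal subject-grouped 5-fold CV inside the
    training set produces out-of-fold positive binary scores (PBS, the 12
    signed OVA learner scores).  Stage 2: an ECOC model trained on the
    concatenated PBS (metrics x 12 = 24 features for two metrics).  At test
    each stage-1 fold model scores the test events and the final label is
    the majority vote over the resulting stage-2 predictions.
    """
    names = list(tables)
    first = tables[names[0]]
    for t in tables.values():
        if not (np.array_equal(t.y, first.y) and np.array_equal(t.groups, first.groups)):
            raise ValueError("feature tables are not aligned on events")
    subjects = np.unique(first.groups)
    rng = np.random.default_rng(seed)
    true_f1, null_f1, reports = [], [], []
    tested = np.zeros(first.n_events, dtype=int)
    correct = np.zeros(first.n_events, dtype=int)
    for _ in range(n_rep):
        train_subj, test_subj = _subject_split(subjects, train_frac, rng)
        _assert_no_leakage(train_subj, test_subj)
        tr = np.isin(first.groups, train_subj)
        te = ~tr
        folds = _group_kfold(train_subj, min(cv_folds, len(train_subj)), rng)

        def _run(y_train: np.ndarray) -> np.ndarray:
            oof_parts, test_parts = [], []
            for name in names:
                tab = tables[name]
                tab_y = tab.y.copy()
                tab_y[tr] = y_train
                shadow = FeatureTable(tab.X, tab_y, tab.groups)
                oof, test_pbs = _stage1_pbs(shadow, tr, te, folds, C)
                oof_parts.append(oof)
                test_parts.append(test_pbs)
            stage2 = EcocModel("ova", C).fit(np.hstack(oof_parts), y_train)
            votes = np.stack([
                stage2.predict(np.hstack([test_parts[m][f] for m in range(len(names))]))
                for f in range(len(folds))])
            return _mode_vote(votes)

        pred = _run(first.y[tr])
        rep = f1_scores(pred, first.y[te], classes=np.unique(first.y))
        true_f1.append(rep.f1_macro)
        reports.append(rep)
        idx = np.where(te)[0]
        tested[idx] += 1
        correct[idx] += (pred == first.y[te]).astype(int)
        if with_null:
            y_null = _scramble_within_subject(first.y[tr], first.groups[tr], rng)
            null_pred = _run(y_null)
            null_f1.append(f1_scores(null_pred, first.y[te],
                                     classes=np.unique(first.y)).f1_macro)
    return HeldOutResult(
        dist=PermutationDistribution(np.asarray(true_f1), np.asarray(null_f1)),
        cv_scores=np.asarray([]), reports=reports,
        event_tested=tested, event_correct=correct, scheme="stack")


# --------------------------------------------------------------------------
# Pairwise binary classification
# --------------------------------------------------------------------------

@dataclass
class PairwiseBinaryResult:
    accuracy: SimilarityMatrix
    association: object            # AssociationResult vs psychometric similarity
    pair_accuracies: dict[tuple, float]


def pairwise_binary_eval(data: FeatureTable, psychometric_sim: SimilarityMatrix,
                         n_rep: int = 10, train_frac: float = 0.75,
                         seed: int = 0, C: float = 1.0) -> PairwiseBinaryResult:
    """Binary held-out accuracy for every task pair vs psychometric similarity.

    Each of the 66 pairs (for 12 tasks) gets the subject-level held-out
    protocol with a single binary linear SVM; the mean accuracies are
    correlated with psychometric similarity with a left-tailed Pearson test
    (behaviourally similar tasks are expected to be harder to separate).
    """
    tasks = np.unique(data.y)
    if len(tasks) != psychometric_sim.n_tasks:
        raise ValueError("task set mismatch with psychometric similarity")
    rng = np.random.default_rng(seed)
    n = len(tasks)
    acc = np.ones((n, n))
    pair_acc = {}
    subjects = np.unique(data.groups)
    for i in range(n):
        for j in range(i + 1, n):
            sel = np.isin(data.y, [tasks[i], tasks[j]])
            sub = data.subset(np.where(sel)[0])
            scores = []
            for _ in range(n_rep):
                tr_s, te_s = _subject_split(subjects, train_frac, rng)
                tr = np.isin(sub.groups, tr_s)
                te = ~tr
                model = EcocModel("ova", C).fit(sub.X[tr], sub.y[tr])
                scores.append(float(np.mean(model.predict(sub.X[te]) == sub.y[te])))
            acc[i, j] = acc[j, i] = float(np.mean(scores))
            pair_acc[(tasks[i], tasks[j])] = acc[i, j]
    acc_sim = SimilarityMatrix(values=acc, kind="accuracy",
                               task_ids=list(tasks))
    assoc = similarity_association_test(psychometric_sim, acc_sim, tail="left")
    return PairwiseBinaryResult(accuracy=acc_sim, association=assoc,
                                pair_accuracies=pair_acc)


# --------------------------------------------------------------------------
# Meta-class evaluation
# --------------------------------------------------------------------------

@dataclass
class MetaClassScheme:
    """Task -> meta-class mapping along one behavioural dimension."""

    dimension: str
    mapping: dict

    def __post_init__(self) -> None:
        if len(set(self.mapping.values())) < 2:
            raise ValueError("degenerate scheme: fewer than 2 meta-classes")

    @property
    def class_sizes(self) -> dict:
        sizes: dict = {}
        for c in self.mapping.values():
            sizes[c] = sizes.get(c, 0) + 1
        return sizes

    def apply(self, y: np.ndarray) -> np.ndarray:
        return np.array([self.mapping[t] for t in y])


@dataclass
class MetaClassResult:
    true_scores: np.ndarray
    null_scores: np.ndarray
    perm_scores: np.ndarray
    p_vs_null: float
    p_vs_perm: float


def metaclass_eval(data: FeatureTable, scheme: MetaClassScheme, n_rep: int = 20,
                   n_perm: int = 100, train_frac: float = 0.75, seed: int = 0,
                   C: float = 1.0) -> MetaClassResult:
    """Meta-class classification vs scrambled-label and size-preserving nulls.

    True and scrambled-label models follow the standard held-out protocol on
    the merged classes; the permutation control reassigns tasks to classes
    at random while keeping every class size fixed, one held-out repetition
    per permutation.
    """
    merged = FeatureTable(data.X, scheme.apply(data.y), data.groups,
                          {**data.meta, "metaclass": scheme.dimension})
    res = repeated_heldout_eval(merged, n_rep=n_rep, train_frac=train_frac,
                                seed=seed, C=C, with_cv=False)
    rng = np.random.default_rng(seed + 1)
    tasks = sorted(scheme.mapping)
    labels = [scheme.mapping[t] for t in tasks]
    perm_scores = []
    for _ in range(n_perm):
        shuffled = [labels[i] for i in rng.permutation(len(labels))]
        pscheme = dict(zip(tasks, shuffled))
        py = np.array([pscheme[t] for t in data.y])
        ptab = FeatureTable(data.X, py, data.groups)
        pres = repeated_heldout_eval(ptab, n_rep=1, train_frac=train_frac,
                                     seed=int(rng.integers(2 ** 31)), C=C,
                                     with_cv=False, with_null=False)
        perm_scores.append(float(pres.dist.true_scores[0]))
    perm_scores = np.asarray(perm_scores)
    p_vs_perm = empirical_p(PermutationDistribution(res.dist.true_scores, perm_scores))
    return MetaClassResult(true_scores=res.dist.true_scores,
                           null_scores=res.dist.null_scores,
                           perm_scores=perm_scores,
                           p_vs_null=res.p, p_vs_perm=p_vs_perm)


# --------------------------------------------------------------------------
# Sparse connection selection
# --------------------------------------------------------------------------

@dataclass
class SparseWeightSummary:
    """Stability of sparse OVA weights across leave-one-subject-out models."""

    pos_frequency: np.ndarray
    neg_frequency: np.ndarray
    top_pos: np.ndarray
    top_neg: np.ndarray
    chosen_C: list
    manifest: dict = field(default_factory=dict)


def _fit_sparse_ova(X: np.ndarray, y: np.ndarray, c_grid: tuple,
                    max_nonzero_frac: float) -> tuple[np.ndarray, float]:
    """One-vs-all L1 logistic weights (classes x features) at the weakest
    penalty keeping the overall nonzero fraction <= max_nonzero_frac."""
    mean, sd = X.mean(axis=0), X.std(axis=0)
    Xs = (X - mean) / np.where(sd > 1e-12, sd, 1.0)
    classes = np.unique(y)
    for C in sorted(c_grid, reverse=True):
        W = np.zeros((len(classes), X.shape[1]))
        for i, c in enumerate(classes):
            clf = LogisticRegression(l1_ratio=1.0, solver="liblinear", C=C,
                                     max_iter=2000, random_state=0)
            clf.fit(Xs, (y == c).astype(int))
            W[i] = clf.coef_[0]
        if np.mean(W != 0) <= max_nonzero_frac:
            return W, C
    warnings.warn("no penalty in the grid reached the sparsity target; "
                  "using the strongest", stacklevel=2)
    return W, C


def sparse_connection_selection(data: FeatureTable,
                                c_grid: tuple = (1.0, 0.3, 0.1, 0.03, 0.01),
                                max_nonzero_frac: float = 0.05,
                                top_percentile: float = 99.9) -> SparseWeightSummary:
    """Leave-one-subject-out sparse OVA models; edge selection frequencies.

    Per held-out subject one L1-logistic OVA model is fit on the rest.  Per
    model and task the positive and negative nonzero weights are binarised
    independently, averaged across tasks, then across models; the top set is
    the edges above the ``top_percentile`` of each frequency map.  Positive
    frequencies flag task-specific edges, negative frequencies task-general
    ones.
    """
    subjects = np.unique(data.groups)
    if len(subjects) < 10:
        raise ValueError("need >= 10 subjects for leave-one-subject-out selection")
    if not np.any(data.X):
        warnings.warn("all-zero features: empty selection", stacklevel=2)
        z = np.zeros(data.X.shape[1])
        return SparseWeightSummary(z, z.copy(), np.array([], dtype=int),
                                   np.array([], dtype=int), [],
                                   {"note": "degenerate all-zero features"})
    pos_maps, neg_maps, chosen = [], [], []
    for s in subjects:
        tr = data.groups != s
        W, C = _fit_sparse_ova(data.X[tr], data.y[tr], c_grid, max_nonzero_frac)
        pos_maps.append((W > 0).mean(axis=0))   # average of binarised maps over tasks
        neg_maps.append((W < 0).mean(axis=0))
        chosen.append(C)
    pos = np.mean(pos_maps, axis=0)
    neg = np.mean(neg_maps, axis=0)
    top_pos = np.where(pos >= np.percentile(pos, top_percentile))[0] if pos.any() \
        else np.array([], dtype=int)
    top_neg = np.where(neg >= np.percentile(neg, top_percentile))[0] if neg.any() \
        else np.array([], dtype=int)
    return SparseWeightSummary(pos, neg, top_pos, top_neg, chosen,
                               {"c_grid": list(c_grid),
                                "max_nonzero_frac": max_nonzero_frac,
                                "top_percentile": top_percentile,
                                "n_models": len(subjects)})
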