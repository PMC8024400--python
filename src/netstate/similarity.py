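"""Task-pairwise similarity measures and their association tests.

Psychometric similarity is a radial-basis kernel on Euclidean distances
between task factor-loading rows, S = exp(-pD^2); spatial similarity is the
Dice overlap of thresholded activation masks; pattern similarity is the
Pearson correlation between task mean-activation vectors.  Similarity
matrices are compared by vectorising their strict upper triangles (66 pairs
for 12 tasks) and applying a one-tailed Pearson test, with Benjamini-
Hochberg FDR across a declared family of tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SimilarityMatrix",
    "psychometric_similarity",
    "dice_coefficient",
    "pattern_similarity",
    "similarity_association_test",
    "associate_family",
    "upper_triangle",
]


@dataclass
class SimilarityMatrix:
    """Symmetric task x task similarity with its provenance kind."""

    values: np.ndarray
    kind: str                      # psychometric | dice | pattern | accuracy
    task_ids: list = None
    cluster_order: np.ndarray | None = None
    scree: np.ndarray | None = None    # explained-variance fractions (pattern)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("similarity matrix must be symmetric")
        self.values = v
        if self.task_ids is None:
            self.task_ids = list(range(v.shape[0]))

    @property
    def n_tasks(self) -> int:
        return self.values.shape[0]


def upper_triangle(values: np.ndarray) -> np.ndarray:
    """Strict upper triangle, row-major: the n(n-1)/2 informative entries."""
    v = np.asarray(values)
    return v[np.triu_indices(v.shape[0], k=1)]


def _cluster_order(similarity: np.ndarray) -> np.ndarray:
    """Average-linkage leaf order on 1 - S, for display."""
    d = 1.0 - similarity
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return leaves_list(average(squareform(d, checks=False)))


def psychometric_similarity(loadings: np.ndarray, task_ids=None) -> SimilarityMatrix:
    """RBF similarity of task factor loadings: S = exp(-pD^2), pD Euclidean."""
    L = np.asarray(loadings, dtype=float)
    if not np.all(np.isfinite(L)):
        raise ValueError("loadings must be finite")
    pd2 = squareform(pdist(L, metric="sqeuclidean"))
    S = np.exp(-pd2)
    return SimilarityMatrix(values=S, kind="psychometric", task_ids=task_ids,
                            cluster_order=_cluster_order(S))


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2*TP / (2*TP + FN + FP) between two binary masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("grid mismatch between masks")
    tp = int((a & b).sum())
    fn = int((a & ~b).sum())
    fp = int((~a & b).sum())
    denom = 2 * tp + fn + fp
    if denom == 0:
        warnings.warn("both masks empty: Dice defined as 0", stacklevel=2)
        return 0.0
    return 2.0 * tp / denom


def dice_matrix(masks: list[np.ndarray], task_ids=None) -> SimilarityMatrix:
    n = len(masks)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = dice_coefficient(masks[i], masks[j])
    return SimilarityMatrix(values=out, kind="dice", task_ids=task_ids)


def pattern_similarity(task_vectors: np.ndarray, task_ids=None) -> SimilarityMatrix:
    """Pearson correlation between task mean-activation vectors, with scree.

    The scree is the eigen-spectrum of the similarity matrix expressed as
    explained-variance fractions; a rank-k activation structure shows k
    non-negligible components.
    """
    V = np.asarray(task_vectors, dtype=float)
    if V.shape[1] < 2:
        raise ValueError("need >= 2 features")
    sd = V.std(axis=1)
    if np.any(sd == 0):
        warnings.warn("constant task vector: correlations undefined (NaN)", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.corrcoef(V)
    finite = np.all(np.isfinite(S))
    scree = None
    if finite:
        eig = np.linalg.eigvalsh(S)[::-1]
        eig = np.clip(eig, 0.0, None)
        scree = eig / eig.sum()
    return SimilarityMatrix(values=S, kind="pattern", task_ids=task_ids,
                            cluster_order=_cluster_order(S) if finite else None,
                            scree=scree)


@dataclass
class AssociationResult:
    r: float
    p: float
    tail: str
    n_pairs: int
    p_fdr: float | None = None


def _one_tailed_pearson(x: np.ndarray, y: np.ndarray, tail: str) -> tuple[float, float]:
    n = len(x)
    if n < 4:
        raise ValueError("need >= 4 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance vector in association test")
    r = float(np.corrcoef(x, y)[0, 1])
    # t transform of r with n - 2 df
    r_c = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r_c * np.sqrt((n - 2) / (1.0 - r_c ** 2))
    if tail == "right":
        p = float(stats.t.sf(t, df=n - 2))
    elif tail == "left":
        p = float(stats.t.cdf(t, df=n - 2))
    else:
        raise ValueError("tail must be 'right' or 'left'")
    return r, p


def similarity_association_test(a: SimilarityMatrix, b: SimilarityMatrix,
                                tail: str = "right") -> AssociationResult:
    """One-tailed Pearson test between the upper triangles of two matrices."""
    if a.n_tasks != b.n_tasks:
        raise ValueError("matrices cover different task sets")
    x = upper_triangle(a.values)
    y = upper_triangle(b.values)
    r, p = _one_tailed_pearson(x, y, tail)
    return AssociationResult(r=r, p=p, tail=tail, n_pairs=len(x))


def associate_family(pairs: list[tuple[SimilarityMatrix, SimilarityMatrix]],
                     tail: str = "right", alpha: float = 0.05) -> list[AssociationResult]:
    """Run a family of association tests with BH-FDR across the family."""
    results = [similarity_association_test(a, b, tail) for a, b in pairs]
    _, p_fdr, _, _ = multipletests([r.p for r in results], alpha=alpha, method="fdr_bh")
    for res, q in zip(results, p_fdr):
        res.p_fdr = float(q)
    return results
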