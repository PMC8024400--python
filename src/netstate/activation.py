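"""Block-design GLM activation mapping.

First-level ordinary-least-squares fits of HRF-convolved block regressors
(one regressor per task block, so the per-block "sum of betas" is a single
coefficient), group one-sample t maps with voxel-level Benjamini-Hochberg
FDR plus a minimal-cluster-size rule, and the conjunction / union / k-way
overlap algebra used to define domain-general cortex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DesignSpec",
    "StatMap",
    "OverlapSummary",
    "double_gamma_hrf",
    "hrf_convolve",
    "build_block_design",
    "estimate_block_betas",
    "group_task_map",
    "overlap_maps",
    "tsnr_qc",
]


# --------------------------------------------------------------------------
# Haemodynamic response
# --------------------------------------------------------------------------

def double_gamma_hrf(t: np.ndarray, peak_s: float = 6.0, undershoot_s: float = 16.0,
                     ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled at times ``t`` (s).

    Peak at ~6 s, undershoot at ~16 s, undershoot amplitude 1/``ratio`` of the
    peak; normalised to unit maximum.
    """
    t = np.asarray(t, dtype=float)
    h = np.zeros_like(t)
    pos = t > 0
    # gamma pdf with unit scale peaks at shape - 1, so shape = delay + 1
    h[pos] = (stats.gamma.pdf(t[pos], peak_s + 1.0)
              - stats.gamma.pdf(t[pos], undershoot_s + 1.0) / ratio)
    peak = h.max()
    if peak > 0:
        h = h / peak
    return h


def hrf_convolve(boxcar: np.ndarray, tr_s: float, **hrf_kwargs) -> np.ndarray:
    """Convolve a frame-sampled boxcar with the canonical HRF (same length out)."""
    n = boxcar.shape[0]
    t = np.arange(0, 32.0 + tr_s, tr_s)
    kernel = double_gamma_hrf(t, **hrf_kwargs)
    return np.convolve(boxcar, kernel)[:n]


# --------------------------------------------------------------------------
# Design construction
# --------------------------------------------------------------------------

@dataclass
class DesignSpec:
    """GLM design: one HRF-convolved column per task block plus nuisance/intercept.

    ``matrix`` is frames x columns; ``task_columns`` maps a column name like
    ``"task-3_block-1"`` to its index; ``block_index`` gives (task, block) per
    task column.
    """

    matrix: np.ndarray
    column_names: list[str]
    task_columns: dict[str, int]
    block_index: list[tuple[object, int]]
    tr_s: float
    frame_count: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("design matrix contains non-finite values")
        for name, j in self.task_columns.items():
            if not np.any(self.matrix[:, j]):
                raise ValueError(f"all-zero task regressor {name!r}")


def build_block_design(events: pd.DataFrame, tr_s: float, frame_count: int,
                       nuisance: np.ndarray | None = None) -> DesignSpec:
    """Build a block design from an events table (onset, duration, trial_type).

    One unit-height boxcar per block, convolved with the canonical HRF; an
    intercept column is always appended, then any nuisance columns.  Onsets
    and durations are in seconds relative to run start.
    """
    run_s = frame_count * tr_s
    cols: list[np.ndarray] = []
    names: list[str] = []
    block_index: list[tuple[object, int]] = []
    seen: dict[object, list[tuple[float, float]]] = {}
    if len(events) == 0:
        warnings.warn("no events: design contains intercept/nuisance only; "
                      "task betas cannot be estimated", stacklevel=2)
    frame_times = np.arange(frame_count) * tr_s
    for task, group in events.groupby("trial_type", sort=True):
        group = group.sort_values("onset")
        for k, (_, row) in enumerate(group.iterrows()):
            onset, dur = float(row["onset"]), float(row["duration"])
            if dur <= 0:
                raise ValueError("block duration must be positive")
            if onset >= run_s:
                raise ValueError(f"onset {onset} s beyond run end ({run_s} s)")
            for o0, d0 in seen.get(task, []):
                if onset < o0 + d0 and o0 < onset + dur:
                    raise ValueError(f"overlapping blocks of task {task!r}")
            seen.setdefault(task, []).append((onset, dur))
            boxcar = ((frame_times >= onset) & (frame_times < onset + dur)).astype(float)
            cols.append(hrf_convolve(boxcar, tr_s))
            names.append(f"task-{task}_block-{k}")
            block_index.append((task, k))
    task_columns = {n: j for j, n in enumerate(names)}
    cols.append(np.ones(frame_count))
    names.append("intercept")
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != frame_count:
            nuisance = nuisance.T
        for j in range(nuisance.shape[1]):
            cols.append(nuisance[:, j])
            names.append(f"nuisance-{j}")
    matrix = np.column_stack(cols)
    return DesignSpec(matrix=matrix, column_names=names, task_columns=task_columns,
                      block_index=block_index, tr_s=tr_s, frame_count=frame_count)


# --------------------------------------------------------------------------
# First-level OLS
# --------------------------------------------------------------------------

def estimate_block_betas(timeseries: np.ndarray, design: DesignSpec) -> pd.DataFrame:
    """OLS per voxel/ROI; one row per (task, block) with the beta vector.

    ``timeseries`` is units x frames (units = voxels or ROIs).  With one basis
    column per block the per-block "sum of betas" aggregate is simply that
    column's coefficient.
    """
    ts = np.atleast_2d(np.asarray(timeseries, dtype=float))
    if ts.shape[1] != design.frame_count:
        raise ValueError(f"frame mismatch: data {ts.shape[1]}, design {design.frame_count}")
    X = design.matrix
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design ({rank} < {X.shape[1]}); collinear columns among "
            f"{design.column_names}")
    coef, *_ = np.linalg.lstsq(X, ts.T, rcond=None)  # columns x units
    records = []
    for (task, block) in design.block_index:
        j = design.task_columns[f"task-{task}_block-{block}"]
        records.append({"task": task, "block": block, "beta": coef[j].copy()})
    return pd.DataFrame(records)


# --------------------------------------------------------------------------
# Group maps
# --------------------------------------------------------------------------

@dataclass
class StatMap:
    """Voxel-wise statistic volume with suprathreshold mask and provenance."""

    statistic: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    threshold_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mask.shape != self.statistic.shape:
            raise ValueError("mask/statistic shape mismatch")
        if np.any(self.mask & ~np.isfinite(self.statistic)):
            raise ValueError("mask covers non-finite statistic voxels")


def _connectivity_structure(ndim: int, connectivity: int) -> np.ndarray:
    if connectivity == 26 or ndim < 3:
        return ndimage.generate_binary_structure(ndim, ndim)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    raise ValueError("connectivity must be one of {6, 18, 26}")


def group_task_map(betas: np.ndarray, alpha: float = 0.05, relaxed_p: float = 0.01,
                   connectivity: int = 26) -> StatMap:
    """Group one-sample t map with FDR + minimal-cluster-size correction.

    ``betas``: subjects x voxel-grid (any spatial shape).  Per voxel a
    one-sample t against 0 (one-sided, activation > 0).  Voxels pass at
    Benjamini-Hochberg FDR ``alpha``; clusters are formed on the relaxed
    uncorrected threshold (positive t, p < ``relaxed_p``); the minimal
    cluster size is the size of the smallest relaxed cluster containing an
    FDR-significant voxel, and the final mask keeps FDR voxels in relaxed
    clusters at least that large.
    """
    betas = np.asarray(betas, dtype=float)
    if betas.shape[0] < 2:
        raise ValueError("group map needs >= 2 subjects")
    vol_shape = betas.shape[1:]
    n = betas.shape[0]
    mean = betas.mean(axis=0)
    sd = betas.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    degenerate = ~np.isfinite(t)
    if np.any(degenerate & (mean != 0)):
        warnings.warn("zero-variance voxels with nonzero mean masked out "
                      "(undefined t)", stacklevel=2)
    p = np.full(vol_shape, 1.0)
    ok = np.isfinite(t)
    p[ok] = stats.t.sf(t[ok], df=n - 1)

    candidate = ok & (t > 0)
    fdr_sig = np.zeros(vol_shape, dtype=bool)
    if candidate.any():
        rej, _, _, _ = multipletests(p[candidate].ravel(), alpha=alpha, method="fdr_bh")
        fdr_sig[candidate] = rej
    relaxed = candidate & (p <= relaxed_p)

    structure = _connectivity_structure(max(len(vol_shape), 1), connectivity)
    if len(vol_shape) == 0:
        raise ValueError("betas must have at least one spatial axis")
    labels, n_clusters = ndimage.label(relaxed, structure=structure if len(vol_shape) > 1
                                       else np.ones(3, dtype=int))
    min_size = None
    mask = np.zeros(vol_shape, dtype=bool)
    if n_clusters:
        sizes = ndimage.sum_labels(np.ones(vol_shape), labels, index=np.arange(1, n_clusters + 1))
        surviving = [c for c in range(1, n_clusters + 1) if fdr_sig[labels == c].any()]
        if surviving:
            min_size = int(min(sizes[c - 1] for c in surviving))
            keep = np.isin(labels, [c for c in range(1, n_clusters + 1)
                                    if sizes[c - 1] >= min_size])
            mask = fdr_sig & keep
    t_clean = np.where(ok, t, np.nan)
    return StatMap(statistic=t_clean, p=p, mask=mask, threshold_meta={
        "alpha": alpha, "relaxed_p": relaxed_p, "correction": "fdr_bh",
        "min_cluster_size": min_size, "connectivity": connectivity,
        "cluster_rule": "per-map minimal FDR cluster", "n_subjects": n,
    })


# --------------------------------------------------------------------------
# Conjunction / union / k-way overlap
# --------------------------------------------------------------------------

@dataclass
class OverlapSummary:
    union_mask: np.ndarray
    intersection_mask: np.ndarray
    intersection_statistic: np.ndarray
    overlap_count: np.ndarray
    kway_percent: dict[int, float]


def overlap_maps(maps: list[StatMap]) -> OverlapSummary:
    """Mask algebra over co-registered statistical maps.

    Intersection = voxelwise AND with the minimum statistic retained on it;
    union = OR; ``overlap_count`` counts the tasks active per voxel and
    ``kway_percent[k]`` is the percentage of union voxels active in exactly
    k tasks.
    """
    if not maps:
        raise ValueError("need at least one map")
    shape = maps[0].mask.shape
    for m in maps:
        if m.mask.shape != shape:
            raise ValueError("grid mismatch between maps")
    stack = np.stack([m.mask for m in maps])
    count = stack.sum(axis=0)
    union = count > 0
    inter = count == len(maps)
    stat = np.where(inter, np.min(np.stack([m.statistic for m in maps]), axis=0), 0.0)
    n_union = int(union.sum())
    kway = {}
    for k in range(1, len(maps) + 1):
        kway[k] = 100.0 * float((count == k).sum()) / n_union if n_union else 0.0
    return OverlapSummary(union_mask=union, intersection_mask=inter,
                          intersection_statistic=stat, overlap_count=count,
                          kway_percent=kway)


# --------------------------------------------------------------------------
# Quality control
# --------------------------------------------------------------------------

def tsnr_qc(timeseries: np.ndarray, cutoff: float = 5.0) -> dict:
    """Temporal SNR (mean/SD per unit, run-level median) with a low-SNR flag."""
    ts = np.atleast_2d(np.asarray(timeseries, dtype=float))
    if ts.shape[1] < 10:
        raise ValueError("need >= 10 frames for tSNR")
    mean = ts.mean(axis=1)
    sd = ts.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = mean / sd
    if np.any(sd == 0):
        warnings.warn("zero-variance series: infinite tSNR reported", stacklevel=2)
        snr = np.where(sd == 0, np.inf, snr)
    run_snr = float(np.median(snr))
    return {"voxel_snr": snr, "run_snr": run_snr, "flagged": bool(run_snr < cutoff)}
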