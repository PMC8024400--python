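"""FIR task-response removal and block-wise dynamic functional connectivity.

Task-evoked mean responses are removed with a finite-impulse-response (FIR)
model — one indicator regressor per post-onset lag, shared across a task's
blocks — rather than an assumed HRF shape, so that co-activation does not
masquerade as connectivity.  Per task block the residual ROI-pair Pearson
correlations are Fisher-z transformed and contrasted against the pooled
rest baseline of the same run, giving one dFC edge vector per
(subject, task, block) event.  A 7-network reduction averages edges into
7 within-network + 21 between-network-pair features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FirResult",
    "fir_regress",
    "pooled_rest_z",
    "block_dfc",
    "rsn_reduce",
    "rsn_feature_names",
    "subject_rsn_features",
    "REST", "DISCARD",
]

REST = -1
DISCARD = -2


@dataclass
class FirResult:
    """Residual time series with per-frame condition labels.

    ``frame_labels``: task id for (haemodynamically shifted) task frames,
    ``REST`` for usable rest frames, ``DISCARD`` for settling frames.
    ``block_frames`` lists (task, block, frame_indices) per event.
    """

    residuals: np.ndarray
    frame_labels: np.ndarray
    block_frames: list[tuple[object, int, np.ndarray]]
    n_fir_columns: int
    rank: int


def fir_regress(roi_ts: np.ndarray, events: pd.DataFrame, tr_s: float,
                lag_count: int | None = None, hrf_shift_frames: int = 2,
                rest_discard_frames: int = 2) -> FirResult:
    """Remove the cross-block mean evoked response per task with an FIR model.

    ``roi_ts`` is ROI x frames for one run; ``events`` has run-relative
    ``onset``/``duration`` seconds and ``trial_type``.  ``lag_count`` defaults
    to block frames + 8 (covers the HRF tail at TR 2 s).  Residuals are from
    an OLS fit of per-task per-lag indicators plus an intercept; condition
    labels shift task windows by ``hrf_shift_frames`` and discard the first
    ``rest_discard_frames`` rest frames after each task offset.
    """
    ts = np.atleast_2d(np.asarray(roi_ts, dtype=float))
    n_frames = ts.shape[1]
    events = events.sort_values("onset") if len(events) else events

    if len(events):
        max_block_frames = int(np.ceil(events["duration"].max() / tr_s))
    else:
        max_block_frames = 0
    if lag_count is None:
        lag_count = max_block_frames + 8
    if max_block_frames and lag_count < max_block_frames:
        raise ValueError("lag window must cover the block duration")

    cols = [np.ones(n_frames)]
    if len(events):
        for task, group in events.groupby("trial_type", sort=True):
            onset_frames = np.round(group["onset"].to_numpy() / tr_s).astype(int)
            for lag in range(lag_count):
                col = np.zeros(n_frames)
                idx = onset_frames + lag
                idx = idx[idx < n_frames]
                if idx.size == 0:
                    continue
                col[idx] = 1.0
                cols.append(col)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn(f"FIR design rank deficient ({rank}/{X.shape[1]}): "
                      "overlapping lag windows; least-squares fit truncates the "
                      "redundant columns", stacklevel=2)
    coef, *_ = np.linalg.lstsq(X, ts.T, rcond=None)
    residuals = ts - (X @ coef).T

    labels = np.full(n_frames, REST, dtype=int)
    block_frames = []
    for _, row in events.iterrows():
        onset_f = int(round(row["onset"] / tr_s)) + hrf_shift_frames
        dur_f = int(round(row["duration"] / tr_s))
        frames = np.arange(onset_f, min(onset_f + dur_f, n_frames))
        labels[frames] = int(row["trial_type"])
        block_frames.append((row["trial_type"], int(row.get("block", 0)), frames))
        tail = np.arange(onset_f + dur_f,
                         min(onset_f + dur_f + rest_discard_frames, n_frames))
        tail = tail[labels[tail] == REST] if tail.size else tail
        labels[tail] = DISCARD
    return FirResult(residuals=residuals, frame_labels=labels,
                     block_frames=block_frames, n_fir_columns=X.shape[1] - 1,
                     rank=int(rank))


def _fisher_z_corr(x: np.ndarray) -> np.ndarray:
    """Upper-triangle Fisher z of the ROI-pair correlations of x (ROI x frames)."""
    if np.any(x.std(axis=1) == 0):
        raise ValueError("constant residual series in correlation window")
    r = np.corrcoef(x)
    iu = np.triu_indices(r.shape[0], k=1)
    return np.arctanh(np.clip(r[iu], -0.999999, 0.999999))


def pooled_rest_z(firs: list[FirResult]) -> np.ndarray:
    """Rest-baseline Fisher z pooled over several runs' rest residual frames.

    Rest is a task-independent steady state, so pooling a subject's rest
    frames across runs gives a far less noisy baseline than the ~20 s rest
    windows of a single run.
    """
    parts = [fir.residuals[:, fir.frame_labels == REST] for fir in firs]
    return _fisher_z_corr(np.concatenate(parts, axis=1))


def block_dfc(fir: FirResult, min_block_frames: int = 10,
              rest_z: np.ndarray | None = None) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-event dFC: task-block Fisher z minus rest-baseline Fisher z.

    The baseline defaults to the pooled rest frames of the same run; pass
    ``rest_z`` (e.g. from :func:`pooled_rest_z`) to use a subject-level
    baseline instead.  Returns (events x edges matrix, events table with
    task/block columns); edge order is the canonical upper triangle of the
    ROI x ROI matrix.
    """
    if rest_z is None:
        rest_frames = np.where(fir.frame_labels == REST)[0]
        if rest_frames.size < min_block_frames:
            raise ValueError("too few rest frames for a baseline")
        z_rest = _fisher_z_corr(fir.residuals[:, rest_frames])
    else:
        z_rest = np.asarray(rest_z, dtype=float)
    rows, vecs = [], []
    for task, block, frames in fir.block_frames:
        if frames.size < min_block_frames:
            raise ValueError(f"task {task} block {block} has {frames.size} frames "
                             f"(< {min_block_frames})")
        z_task = _fisher_z_corr(fir.residuals[:, frames])
        vecs.append(z_task - z_rest)
        rows.append({"task": task, "block": block, "n_frames": int(frames.size)})
    return np.stack(vecs), pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Resting-state-network reduction
# --------------------------------------------------------------------------

def rsn_feature_names(network_names: list[str]) -> list[str]:
    n = len(network_names)
    names = [f"within_{network_names[a]}" for a in range(n)]
    names += [f"between_{network_names[a]}-{network_names[b]}"
              for a in range(n) for b in range(a + 1, n)]
    return names


def rsn_reduce(dfc: np.ndarray, network_labels: np.ndarray,
               n_networks: int = 7) -> np.ndarray:
    """Average edges into within- and between-network features.

    ``dfc`` is an edge vector or events x edges matrix in canonical upper-
    triangle order over K ROIs; returns n_networks + C(n_networks, 2)
    features per row (28 for 7 networks).  A network with < 2 ROIs has an
    undefined within feature, reported as NaN with a warning.
    """
    dfc = np.atleast_2d(np.asarray(dfc, dtype=float))
    labels = np.asarray(network_labels)
    K = labels.shape[0]
    if dfc.shape[1] != K * (K - 1) // 2:
        raise ValueError("edge vector length does not match label count")
    if labels.min() < 0 or labels.max() >= n_networks:
        raise ValueError("network labels must be in [0, n_networks)")
    iu_i, iu_j = np.triu_indices(K, k=1)
    li, lj = labels[iu_i], labels[iu_j]
    n_between = n_networks * (n_networks - 1) // 2
    out = np.full((dfc.shape[0], n_networks + n_between), np.nan)
    for a in range(n_networks):
        sel = (li == a) & (lj == a)
        if sel.any():
            out[:, a] = dfc[:, sel].mean(axis=1)
        else:
            warnings.warn(f"network {a} has < 2 ROIs: within feature undefined",
                          stacklevel=2)
    col = n_networks
    for a in range(n_networks):
        for b in range(a + 1, n_networks):
            sel = ((li == a) & (lj == b)) | ((li == b) & (lj == a))
            if sel.any():
                out[:, col] = dfc[:, sel].mean(axis=1)
            col += 1
    return out


def subject_rsn_features(rsn_features: np.ndarray, subjects: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Subject-level vectors: mean across each subject's events (36 at study scale)."""
    rsn_features = np.asarray(rsn_features, dtype=float)
    subjects = np.asarray(subjects)
    ids = np.unique(subjects)
    out = np.stack([rsn_features[subjects == s].mean(axis=0) for s in ids])
    return out, ids
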