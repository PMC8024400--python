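"""Synthetic block-design fMRI cohorts with planted network states.

Emulates the study design the pipeline targets: 60 subjects x 12 cognitive
tasks x 3 one-minute blocks separated by 20 s rest at TR = 2 s.  Each task
evokes (a) an activation pattern and (b) a connectivity state, both built as
a mixture of a shared (domain-general) component, a factor-prototype
component organised by a 3-factor psychometric structure, and a task-unique
component.  Task-unique connectivity mass is placed predominantly on
between-network edges and shared mass on within-network edges.  A per-subject
fidelity parameter phi in [0, 1] scales how strongly the subject expresses
the task state, and behavioural scores are a noisy linear function of phi —
so downstream classifiability and the behavioural performance index have a
common planted cause.

ROI time series are drawn per condition from the condition correlation
matrix (rest = baseline; task = baseline + phi-scaled Fisher-z perturbation)
with AR(1) temporal smoothing, plus an HRF-convolved activation boxcar and
white measurement noise.  Everything is reproducible from explicit seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .activation import hrf_convolve

__all__ = [
    "SimConfig",
    "GroundTruth",
    "CohortDataset",
    "PositiveDefiniteError",
    "generate_ground_truth",
    "simulate_cohort",
    "make_cohort",
    "RSN_NAMES",
]

RSN_NAMES = ("DM", "DA", "FP", "LI", "SM", "VA", "VS")


class PositiveDefiniteError(ValueError):
    """A planted condition correlation matrix is not positive definite."""


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Cohort design parameters (defaults mirror the study design)."""

    n_subjects: int = 60
    n_tasks: int = 12
    n_factors: int = 3
    n_rois: int = 40
    n_networks: int = 7
    blocks_per_task: int = 3
    block_s: float = 60.0
    rest_s: float = 20.0
    tr_s: float = 2.0
    voxels_per_roi: int = 0
    noise_sd: float = 0.25
    voxel_noise_sd: float = 0.5
    ar_rho: float = 0.3
    seed: int = 0
    # mixture weights / amplitudes of the planted states
    shared_weight: float = 1.0
    factor_weight: float = 1.0
    unique_weight: float = 1.0
    shared_conn_amp: float = 0.06
    factor_conn_amp: float = 0.20
    unique_conn_amp: float = 0.30
    factor_conn_edges_per_roi: float = 0.4
    unique_conn_edges_per_roi: float = 0.25
    between_edge_bias: float = 0.85
    shared_act_amp: float = 0.5
    factor_act_amp: float = 0.20
    unique_act_amp: float = 0.12
    baseline_within_r: float = 0.25
    baseline_between_r: float = 0.06
    fidelity_range: tuple[float, float] = (0.3, 1.0)
    behaviour_noise_sd: float = 0.3

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_tasks", "n_factors", "n_rois", "n_networks",
                     "blocks_per_task"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for dur in (self.block_s, self.rest_s):
            if abs(dur / self.tr_s - round(dur / self.tr_s)) > 1e-9:
                raise ValueError("block_s and rest_s must be divisible by tr_s")
        if not (0.0 <= self.fidelity_range[0] <= self.fidelity_range[1] <= 1.0):
            raise ValueError("fidelity_range must lie within [0, 1]")

    @property
    def block_frames(self) -> int:
        return int(round(self.block_s / self.tr_s))

    @property
    def rest_frames(self) -> int:
        return int(round(self.rest_s / self.tr_s))

    @property
    def frames_per_run(self) -> int:
        # [rest, block] x blocks_per_task
        return self.blocks_per_task * (self.rest_frames + self.block_frames)

    @property
    def n_edges(self) -> int:
        return self.n_rois * (self.n_rois - 1) // 2


# --------------------------------------------------------------------------
# Ground truth
# --------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Planted generative state of a cohort.

    ``task_connectivity`` rows are Fisher-z edge perturbations of the baseline
    (rest) correlation structure; ``task_activation`` rows are mean BOLD
    amplitudes per ROI; ``fidelity`` is phi per subject.
    """

    factor_loadings: np.ndarray        # tasks x factors, rows unit-norm, >= 0
    task_factor: np.ndarray            # dominant factor id per task
    task_activation: np.ndarray        # tasks x rois
    task_connectivity: np.ndarray      # tasks x edges (Fisher z)
    shared_connectivity: np.ndarray    # edges
    baseline_z: np.ndarray             # edges, Fisher z of rest correlations
    rsn_labels: np.ndarray             # roi -> network id (0..n_networks-1)
    fidelity: np.ndarray               # subject -> phi in [0, 1]
    behaviour_noise_sd: float
    behaviour_weights: np.ndarray = field(default=None)  # per-task slope on phi
    behaviour_offsets: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if np.any(self.factor_loadings < 0):
            raise ValueError("factor loadings must be non-negative")
        norms = np.linalg.norm(self.factor_loadings, axis=1)
        if not np.allclose(norms, 1.0):
            raise ValueError("factor loading rows must be unit-norm")
        if np.any((self.fidelity < 0) | (self.fidelity > 1)):
            raise ValueError("fidelity values must lie in [0, 1]")


def edge_index(n_rois: int) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle (i, j) endpoints in the canonical edge order."""
    return np.triu_indices(n_rois, k=1)


def _square_from_edges(z: np.ndarray, n_rois: int) -> np.ndarray:
    out = np.zeros((n_rois, n_rois))
    iu = np.triu_indices(n_rois, k=1)
    out[iu] = z
    return out + out.T


def condition_correlation(gt: GroundTruth, task: int | None, phi: float = 1.0) -> np.ndarray:
    """Planted correlation matrix for rest (``task=None``) or a task at fidelity phi."""
    z = gt.baseline_z.copy()
    if task is not None:
        z = z + phi * gt.task_connectivity[task]
    n = gt.rsn_labels.shape[0]
    corr = np.tanh(_square_from_edges(z, n))
    np.fill_diagonal(corr, 1.0)
    return corr


def _check_pd(corr: np.ndarray, what: str) -> None:
    eigmin = float(np.linalg.eigvalsh(corr)[0])
    if eigmin <= 1e-10:
        raise PositiveDefiniteError(
            f"{what}: implied correlation matrix not positive definite "
            f"(min eigenvalue {eigmin:.3e}); reduce the connectivity "
            f"perturbation amplitudes or the between/within baseline contrast")


def generate_ground_truth(config: SimConfig, rng_seed: int | None = None) -> GroundTruth:
    """Draw a planted cohort state consistent with ``config``.

    Task states decompose as shared + factor-prototype + task-unique
    components with the configured mixing weights; every implied condition
    correlation matrix is checked for positive definiteness at phi = 1.
    """
    rng = np.random.default_rng(config.seed if rng_seed is None else rng_seed)
    T, F, R = config.n_tasks, config.n_factors, config.n_rois

    # -- psychometric factor structure: tasks split evenly across factors,
    #    dominant loading ~0.9 with small positive off-factor loadings.
    task_factor = np.arange(T) % F
    loadings = np.zeros((T, F))
    for t in range(T):
        row = 0.12 + 0.10 * rng.random(F)
        row[task_factor[t]] = 0.9 + 0.08 * rng.random()
        loadings[t] = row / np.linalg.norm(row)

    # -- ROI -> network assignment (contiguous blocks, all networks non-empty)
    rsn_labels = np.sort(np.arange(R) % config.n_networks)

    # -- baseline (rest) correlations: within-network > between-network
    iu_i, iu_j = edge_index(R)
    within = rsn_labels[iu_i] == rsn_labels[iu_j]
    baseline_r = np.where(within, config.baseline_within_r, config.baseline_between_r)
    baseline_z = np.arctanh(baseline_r)

    # -- shared connectivity component: within-network task-general coupling change
    shared = np.zeros(config.n_edges)
    shared[within] = config.shared_conn_amp

    # -- factor prototypes and task-unique components: sparse signed patterns,
    #    biased toward between-network edges (bias = fraction of mass between)
    # edge counts scale with R (not with edge count) so the perturbation's
    # spectral norm stays bounded relative to the baseline's smallest eigenvalue
    def _sparse_pattern(amp: float, k: float, bias: float) -> np.ndarray:
        p_between = np.where(within, 1.0 - bias, bias)
        p_between = p_between / p_between.sum()
        k = min(max(1, int(round(k))), config.n_edges)
        idx = rng.choice(config.n_edges, size=k, replace=False, p=p_between)
        vec = np.zeros(config.n_edges)
        vec[idx] = amp * rng.choice([-1.0, 1.0], size=k)
        return vec

    def _draw_connectivity() -> np.ndarray:
        factor_protos = np.stack([
            _sparse_pattern(config.factor_conn_amp,
                            config.factor_conn_edges_per_roi * R, 0.6)
            for _ in range(F)])
        unique = np.stack([
            _sparse_pattern(config.unique_conn_amp,
                            config.unique_conn_edges_per_roi * R,
                            config.between_edge_bias)
            for _ in range(T)])
        return (config.shared_weight * shared[None, :]
                + config.factor_weight * factor_protos[task_factor]
                + config.unique_weight * unique)

    # rejection sampling at the requested perturbation scale: redraw the sparse
    # patterns until every condition correlation matrix is positive definite
    fid_hi = config.fidelity_range[1]
    task_connectivity = None
    last_err: Exception | None = None
    for _ in range(25):
        candidate = _draw_connectivity()
        try:
            for t in range(T):
                z = baseline_z + fid_hi * candidate[t]
                corr = np.tanh(_square_from_edges(z, R))
                np.fill_diagonal(corr, 1.0)
                _check_pd(corr, f"task {t}")
            task_connectivity = candidate
            break
        except PositiveDefiniteError as err:
            last_err = err
    if task_connectivity is None:
        raise PositiveDefiniteError(
            "positive definiteness could not be achieved at the requested "
            f"perturbation scale after 25 redraws; last failure: {last_err}")

    # -- activation: shared profile on all ROIs + factor + unique ROI subsets
    shared_act = config.shared_act_amp * (0.5 + rng.random(R))
    factor_act = np.stack([config.factor_act_amp * (rng.random(R) < 0.3) *
                           (0.5 + rng.random(R)) for _ in range(F)])
    unique_act = np.stack([config.unique_act_amp * (rng.random(R) < 0.2) *
                           (0.5 + rng.random(R)) for _ in range(T)])
    task_activation = (config.shared_weight * shared_act[None, :]
                       + config.factor_weight * factor_act[task_factor]
                       + config.unique_weight * unique_act)

    fid_lo, _ = config.fidelity_range
    fidelity = fid_lo + (fid_hi - fid_lo) * rng.random(config.n_subjects)

    behaviour_weights = 1.0 + 0.2 * rng.standard_normal(T) * 0.5
    behaviour_offsets = 10.0 + rng.standard_normal(T)

    gt = GroundTruth(factor_loadings=loadings, task_factor=task_factor,
                     task_activation=task_activation,
                     task_connectivity=task_connectivity,
                     shared_connectivity=config.shared_weight * shared,
                     baseline_z=baseline_z, rsn_labels=rsn_labels,
                     fidelity=fidelity,
                     behaviour_noise_sd=config.behaviour_noise_sd,
                     behaviour_weights=behaviour_weights,
                     behaviour_offsets=behaviour_offsets)

    _check_pd(condition_correlation(gt, None), "rest")
    return gt


# --------------------------------------------------------------------------
# Cohort simulation
# --------------------------------------------------------------------------

@dataclass
class CohortDataset:
    """Simulated cohort: ROI runs, events, behaviour, and its ground truth.

    ``roi_timeseries`` is subject x ROI x time with the 12 task runs
    concatenated in task order (``frames_per_run`` frames each); ``events``
    holds one row per task block with onsets global to that concatenation.
    """

    roi_timeseries: np.ndarray
    events: pd.DataFrame
    behaviour: pd.DataFrame            # subjects x tasks
    ground_truth: GroundTruth
    config: SimConfig
    voxel_timeseries: np.ndarray | None = None
    roi_voxel_map: np.ndarray | None = None

    @property
    def frames_per_run(self) -> int:
        return self.config.frames_per_run

    def run_slice(self, task: int) -> slice:
        f = self.frames_per_run
        return slice(task * f, (task + 1) * f)

    def run_events(self, subject: int, task: int) -> pd.DataFrame:
        """Events of one run with onsets relative to run start."""
        ev = self.events
        sel = ev[(ev.subject == subject) & (ev.task == task)].copy()
        sel["onset"] = sel["onset"] - task * self.frames_per_run * self.config.tr_s
        return sel


def _run_condition_labels(config: SimConfig) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Per-frame task flag for one run plus (onset_s, duration_s) per block."""
    task_on = np.zeros(config.frames_per_run, dtype=bool)
    blocks = []
    f = 0
    for _ in range(config.blocks_per_task):
        f += config.rest_frames
        task_on[f:f + config.block_frames] = True
        blocks.append((f * config.tr_s, config.block_s))
        f += config.block_frames
    return task_on, blocks


def _sample_run(rng: np.random.Generator, config: SimConfig, chol_rest: np.ndarray,
                chol_task: np.ndarray, activation: np.ndarray,
                task_on: np.ndarray, blocks: list[tuple[float, float]]) -> np.ndarray:
    """One run: AR(1)-smoothed condition-covariance noise + HRF-convolved activation."""
    n_frames = config.frames_per_run
    R = config.n_rois
    innov = rng.standard_normal((n_frames, R))
    x = np.empty((n_frames, R))
    rho = config.ar_rho
    scale = np.sqrt(1.0 - rho ** 2)
    prev = innov[0] @ (chol_task if task_on[0] else chol_rest).T
    x[0] = prev
    for f in range(1, n_frames):
        chol = chol_task if task_on[f] else chol_rest
        e = innov[f] @ chol.T
        prev = rho * prev + scale * e
        x[f] = prev
    # activation: unit boxcar over the blocks, HRF convolved, scaled per ROI
    boxcar = task_on.astype(float)
    evoked = hrf_convolve(boxcar, config.tr_s)
    x += evoked[:, None] * activation[None, :]
    if config.noise_sd > 0:
        x += config.noise_sd * rng.standard_normal((n_frames, R))
    return x.T  # ROI x time


def simulate_cohort(gt: GroundTruth, config: SimConfig,
                    rng_seed: int | None = None) -> CohortDataset:
    """Simulate every subject's 12 runs plus behaviour from a ground truth."""
    if gt.task_connectivity.shape != (config.n_tasks, config.n_edges):
        raise ValueError("ground truth inconsistent with config dimensions")
    if gt.fidelity.shape[0] != config.n_subjects:
        raise ValueError("fidelity length != n_subjects")
    rng = np.random.default_rng(config.seed + 1 if rng_seed is None else rng_seed)
    S, T, R = config.n_subjects, config.n_tasks, config.n_rois
    task_on, blocks = _run_condition_labels(config)

    corr_rest = condition_correlation(gt, None)
    if not np.all(np.isfinite(corr_rest)):
        raise ValueError("non-finite baseline covariance")
    chol_rest = np.linalg.cholesky(corr_rest)

    data = np.empty((S, R, T * config.frames_per_run))
    event_rows = []
    for s in range(S):
        phi = float(gt.fidelity[s])
        for t in range(T):
            corr_t = condition_correlation(gt, t, phi=phi)
            chol_t = np.linalg.cholesky(corr_t)
            run = _sample_run(rng, config, chol_rest, chol_t,
                              phi * gt.task_activation[t], task_on, blocks)
            data[s, :, t * config.frames_per_run:(t + 1) * config.frames_per_run] = run
            run_offset_s = t * config.frames_per_run * config.tr_s
            for b, (onset_s, dur_s) in enumerate(blocks):
                event_rows.append({"subject": s, "task": t, "block": b,
                                   "onset": run_offset_s + onset_s,
                                   "duration": dur_s, "trial_type": t})
    events = pd.DataFrame(event_rows)

    # behaviour: score_st = offset_t + weight_t * phi_s + noise
    scores = (gt.behaviour_offsets[None, :]
              + gt.behaviour_weights[None, :] * gt.fidelity[:, None])
    if gt.behaviour_noise_sd > 0:
        scores = scores + gt.behaviour_noise_sd * rng.standard_normal((S, T))
    behaviour = pd.DataFrame(scores, columns=[f"task-{t}" for t in range(T)])
    behaviour.index.name = "subject"

    voxel_ts = None
    roi_voxel_map = None
    if config.voxels_per_roi > 0:
        roi_voxel_map = np.repeat(np.arange(R), config.voxels_per_roi)
        voxel_ts = data[:, roi_voxel_map, :]
        if config.voxel_noise_sd > 0:
            voxel_ts = voxel_ts + config.voxel_noise_sd * rng.standard_normal(voxel_ts.shape)

    return CohortDataset(roi_timeseries=data, events=events, behaviour=behaviour,
                         ground_truth=gt, config=config,
                         voxel_timeseries=voxel_ts, roi_voxel_map=roi_voxel_map)


def make_cohort(config: SimConfig | None = None, seed: int | None = None,
                **overrides) -> CohortDataset:
    """Convenience: ground truth + cohort in one call (seeded)."""
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        config = SimConfig(**{**asdict(config), **overrides})
    if seed is not None:
        config = SimConfig(**{**asdict(config), "seed": seed})
    gt = generate_ground_truth(config)
    return simulate_cohort(gt, config)


# --------------------------------------------------------------------------
# On-disk layout (BIDS-flavoured, plain text)
# --------------------------------------------------------------------------

def write_cohort(cohort: CohortDataset, out_dir: str | Path) -> Path:
    """Write a cohort to a BIDS-flavoured text layout.

    Per subject/run: an events TSV (onset, duration, trial_type relative to
    run start) and, when the voxel layer is absent, the ROI time series as
    TSV.  Cohort-level: participants.tsv (fidelity), behaviour.csv,
    ground_truth.json and config.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = cohort.config
    for s in range(cfg.n_subjects):
        sub = out / f"sub-{s:02d}"
        sub.mkdir(exist_ok=True)
        for t in range(cfg.n_tasks):
            ev = cohort.run_events(s, t)[["onset", "duration", "trial_type"]]
            ev.to_csv(sub / f"sub-{s:02d}_task-{t:02d}_events.tsv", sep="\t", index=False)
            ts = cohort.roi_timeseries[s, :, cohort.run_slice(t)]
            pd.DataFrame(ts.T, columns=[f"roi-{r}" for r in range(cfg.n_rois)]).to_csv(
                sub / f"sub-{s:02d}_task-{t:02d}_bold.tsv", sep="\t", index=False)
    pd.DataFrame({"participant_id": [f"sub-{s:02d}" for s in range(cfg.n_subjects)],
                  "fidelity": cohort.ground_truth.fidelity}).to_csv(
        out / "participants.tsv", sep="\t", index=False)
    cohort.behaviour.to_csv(out / "behaviour.csv")
    gt = cohort.ground_truth
    with open(out / "ground_truth.json", "w") as fh:
        json.dump({k: (v.tolist() if isinstance(v, np.ndarray) else v)
                   for k, v in asdict(gt).items()}, fh)
    with open(out / "config.json", "w") as fh:
        json.dump({k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()}, fh)
    return out
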