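"""Watershed parcellation of statistical volumes and ROI signal extraction.

The segmentation is an intensity-inverted watershed: flooding starts from
the local maxima of the (optionally smoothed) statistic restricted to the
suprathreshold mask and descends in statistic order, so ROI boundaries fall
along the troughs between peaks.  Determinism is guaranteed by breaking all
ties (plateaus, equal-statistic frontier voxels) by lexicographic voxel
index.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .activation import StatMap, _connectivity_structure

__all__ = ["Parcellation", "watershed_parcellate", "extract_roi_signals"]


@dataclass
class Parcellation:
    """Integer label volume partitioning a mask into ROIs (0 = background)."""

    labels: np.ndarray
    roi_ids: np.ndarray
    roi_sizes: np.ndarray
    seed_coords: dict[int, tuple[int, ...]]
    provenance: dict = field(default_factory=dict)

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)


def _neighbours(idx: tuple[int, ...], shape: tuple[int, ...],
                offsets: np.ndarray) -> list[tuple[int, ...]]:
    out = []
    for off in offsets:
        nb = tuple(int(i + o) for i, o in zip(idx, off))
        if all(0 <= v < s for v, s in zip(nb, shape)):
            out.append(nb)
    return out


def _structure_offsets(ndim: int, connectivity: int) -> np.ndarray:
    structure = _connectivity_structure(ndim, connectivity)
    offs = np.argwhere(structure) - 1
    return offs[np.any(offs != 0, axis=1)]


def _find_seeds(stat: np.ndarray, mask: np.ndarray, offsets: np.ndarray) -> list[tuple[int, ...]]:
    """One seed per local-maximum plateau: the lexicographically smallest voxel
    of every connected equal-value region with no strictly higher neighbour."""
    shape = stat.shape
    coords = [tuple(c) for c in np.argwhere(mask)]
    visited = np.zeros(shape, dtype=bool)
    seeds = []
    for c in coords:  # argwhere order is lexicographic
        if visited[c]:
            continue
        # flood the equal-value plateau containing c
        value = stat[c]
        plateau = [c]
        visited[c] = True
        stack = [c]
        is_max = True
        while stack:
            cur = stack.pop()
            for nb in _neighbours(cur, shape, offsets):
                if not mask[nb]:
                    continue
                if stat[nb] > value:
                    is_max = False
                elif stat[nb] == value and not visited[nb]:
                    visited[nb] = True
                    plateau.append(nb)
                    stack.append(nb)
        if is_max:
            seeds.append(min(plateau))
    return sorted(seeds)


def watershed_parcellate(stat_map: StatMap, connectivity: int = 26,
                         min_size: int = 10, smooth_fwhm: float = 0.0,
                         voxel_size_mm: float = 1.0) -> Parcellation:
    """Segment a statistical map's mask into ROIs around its local maxima.

    Flooding assigns every mask voxel to exactly one ROI; ROIs smaller than
    ``min_size`` are merged into the neighbouring ROI with the highest
    statistic on the shared boundary, or discarded (with a warning) when they
    touch no other ROI.
    """
    mask = np.asarray(stat_map.mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: nothing to parcellate")
    stat = np.array(stat_map.statistic, dtype=float)
    stat[~np.isfinite(stat)] = -np.inf
    if smooth_fwhm > 0:
        sigma = smooth_fwhm / voxel_size_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        stat = ndimage.gaussian_filter(np.where(mask, stat, 0.0), sigma=sigma)
    offsets = _structure_offsets(stat.ndim, connectivity)

    seeds = _find_seeds(stat, mask, offsets)
    labels = np.zeros(mask.shape, dtype=np.int32)
    heap: list[tuple[float, tuple[int, ...], int]] = []
    counter = 0
    for lab, seed in enumerate(seeds, start=1):
        heapq.heappush(heap, (-stat[seed], seed, lab))
    # priority flood: highest statistic first, lexicographic tie-break on voxel
    while heap:
        _, idx, lab = heapq.heappop(heap)
        if labels[idx]:
            continue
        labels[idx] = lab
        for nb in _neighbours(idx, mask.shape, offsets):
            if mask[nb] and not labels[nb]:
                heapq.heappush(heap, (-stat[nb], nb, lab))
        counter += 1

    # merge undersized ROIs
    def _sizes() -> dict[int, int]:
        ids, counts = np.unique(labels[labels > 0], return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    sizes = _sizes()
    changed = True
    while changed:
        changed = False
        for lab in sorted(sizes):
            if sizes[lab] >= min_size:
                continue
            region = labels == lab
            best, best_stat = 0, -np.inf
            for idx in map(tuple, np.argwhere(region)):
                for nb in _neighbours(idx, mask.shape, offsets):
                    other = labels[nb]
                    if other and other != lab:
                        boundary_stat = max(stat[idx], stat[nb])
                        if (boundary_stat > best_stat
                                or (boundary_stat == best_stat and other < best)):
                            best, best_stat = other, boundary_stat
            if best:
                labels[region] = best
            else:
                warnings.warn(f"isolated ROI of {sizes[lab]} voxels (< min_size) "
                              "discarded", stacklevel=2)
                labels[region] = 0
            sizes = _sizes()
            changed = True
            break

    # relabel contiguously in seed order
    kept = sorted(sizes)
    remap = {old: new for new, old in enumerate(kept, start=1)}
    out = np.zeros_like(labels)
    seed_coords = {}
    for old, new in remap.items():
        out[labels == old] = new
        seed_coords[new] = seeds[old - 1]
    ids, counts = np.unique(out[out > 0], return_counts=True)
    return Parcellation(labels=out, roi_ids=ids, roi_sizes=counts,
                        seed_coords=seed_coords,
                        provenance={"connectivity": connectivity, "min_size": min_size,
                                    "smooth_fwhm": smooth_fwhm,
                                    "threshold_meta": stat_map.threshold_meta})


def extract_roi_signals(data: np.ndarray, parc: Parcellation) -> np.ndarray:
    """Mean over member voxels per ROI.

    ``data`` is voxel-grid x trailing axis (time or events): shape
    ``parc.labels.shape + (n,)`` or, for flat data, ``(n_voxels, n)`` with
    ``parc.labels`` 1-D.  Returns ROI x n in ``roi_ids`` order.
    """
    data = np.asarray(data, dtype=float)
    vol_ndim = parc.labels.ndim
    if data.shape[:vol_ndim] != parc.labels.shape:
        raise ValueError("data grid does not match parcellation grid")
    flat = data.reshape(-1, *data.shape[vol_ndim:])
    if flat.ndim == 1:
        flat = flat[:, None]
    lab = parc.labels.reshape(-1)
    out = np.empty((parc.n_rois, flat.shape[1]))
    for k, roi in enumerate(parc.roi_ids):
        members = lab == roi
        if not members.any():
            raise ValueError(f"ROI {roi} has no in-grid voxels")
        out[k] = flat[members].mean(axis=0)
    return out
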