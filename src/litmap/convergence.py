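"""Convergence of meta-analytic results across research fields.

Per-community cluster-level significance masks are overlapped voxel-wise;
voxels where >= 4 (or 5) communities are significant, at EVERY semantic
granularity level analyzed, form the robustness mask, whose connected
components are the convergence regions of interest (ROIs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .ale import VoxelMap, _connectivity_structure
from .grid import BrainGrid, ConfigError

__all__ = [
    "OverlapMap",
    "RobustnessMask",
    "ROI",
    "overlap_map",
    "robustness_conjunction",
    "center_of_mass",
    "rois_from_robustness",
]


@dataclass
class OverlapMap:
    """Per-voxel count of communities whose significance mask covers it."""

    grid: BrainGrid
    counts: np.ndarray
    masks: dict[object, np.ndarray]

    def contributors(self, ijk: tuple[int, int, int]) -> set:
        return {c for c, m in self.masks.items() if m[ijk]}


@dataclass
class RobustnessMask:
    """Voxels with >= threshold communities overlapping at every granularity."""

    grid: BrainGrid
    mask: np.ndarray
    threshold: int
    granularities: list


def _as_mask(m, grid: BrainGrid) -> np.ndarray:
    arr = m.values.astype(bool) if isinstance(m, VoxelMap) else np.asarray(m, dtype=bool)
    if arr.shape != tuple(grid.shape):
        raise ConfigError("sig_masks: grid mismatch")
    return arr


def overlap_map(sig_masks: dict) -> OverlapMap:
    """Voxel-wise overlap count across community significance masks."""
    if not sig_masks:
        raise ConfigError("sig_masks: empty")
    first = next(iter(sig_masks.values()))
    grid = first.grid if isinstance(first, VoxelMap) else None
    if grid is None:
        raise ConfigError("sig_masks: pass VoxelMaps (or provide a grid via VoxelMap)")
    masks = {c: _as_mask(m, grid) for c, m in sig_masks.items()}
    counts = np.zeros(grid.shape, dtype=np.int64)
    for m in masks.values():
        counts += m
    return OverlapMap(grid, counts, masks)


def robustness_conjunction(
    overlap_maps: dict[object, OverlapMap], threshold: int
) -> RobustnessMask:
    """Conjunction across granularity levels of >= threshold overlap.

    A voxel survives iff its overlap count reaches ``threshold`` at every
    granularity; the result therefore shrinks (or stays equal) as levels
    are added, and a higher threshold gives a subset mask.
    """
    if len(overlap_maps) < 2:
        raise ConfigError("overlap_maps: need >= 2 granularity levels")
    grids = list(overlap_maps.values())
    grid = grids[0].grid
    out = np.ones(grid.shape, dtype=bool)
    for om in grids:
        if om.grid.shape != grid.shape:
            raise ConfigError("overlap_maps: grid mismatch")
        out &= om.counts >= threshold
    return RobustnessMask(grid, out, threshold, list(overlap_maps.keys()))


def center_of_mass(mask_or_voxels, grid: BrainGrid) -> np.ndarray:
    """Unweighted mean of member voxel centers, in mm.

    Accepts a boolean mask over the grid or an (n, 3) array of voxel
    indices; raises on an empty set.
    """
    arr = np.asarray(mask_or_voxels)
    if arr.dtype == bool:
        vox = np.argwhere(arr)
    else:
        vox = np.atleast_2d(arr)
    if len(vox) == 0:
        raise ConfigError("mask_or_voxels: empty voxel set")
    return grid.voxel_to_mm(vox.mean(axis=0)[None, :])[0]


@dataclass
class ROI:
    roi_id: int
    voxels: np.ndarray  # (n, 3) indices
    com_mm: np.ndarray

    @property
    def size(self) -> int:
        return len(self.voxels)

    def as_mask(self, grid: BrainGrid) -> np.ndarray:
        out = np.zeros(grid.shape, dtype=bool)
        out[self.voxels[:, 0], self.voxels[:, 1], self.voxels[:, 2]] = True
        return out


def rois_from_robustness(
    robustness: RobustnessMask, connectivity: int = 26
) -> list[ROI]:
    """Connected components of the robustness mask, largest first."""
    labels, n = ndimage.label(robustness.mask, structure=_connectivity_structure(connectivity))
    rois = []
    for lab in range(1, n + 1):
        vox = np.argwhere(labels == lab)
        rois.append(ROI(0, vox, center_of_mass(vox, robustness.grid)))
    rois.sort(key=lambda r: (-r.size, tuple(r.voxels[0])))
    for i, r in enumerate(rois, start=1):
        r.roi_id = i
    return rois
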