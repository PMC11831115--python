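"""Region-level specificity: is meta-analytic activation in an ROI specific
to the query-matched literature?

The statistic is the cluster mass — the sum of the voxel-wise z values
(normal-quantile transform of the analytic ALE p) over a fixed ROI,
UNthresholded. The null is Monte-Carlo: repeatedly draw equally many
studies from a reference pool of non-matching articles, rerun the ALE to a
z map, and record the ROI mass; the add-one Monte-Carlo p compares the
observed mass to this null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri

from .ale import (
    ALEParams,
    CoordinateStudy,
    MAX_Z,
    _P_FLOOR,
    _tail_from_probs,
    ale_null_distribution,
    ma_map,
)
from .convergence import ROI
from .grid import BrainGrid, ConfigError

__all__ = ["SpecificityResult", "cluster_mass", "specificity_test"]


@dataclass
class SpecificityResult:
    roi_id: int
    observed_mass: float
    null_masses: np.ndarray
    p_mc: float
    n_iter: int
    seed: int


def cluster_mass(z_map, roi) -> float:
    """Sum of z over the ROI's voxels (additive over any ROI partition)."""
    grid = z_map.grid
    if isinstance(roi, ROI):
        vox = roi.voxels
    else:
        arr = np.asarray(roi)
        vox = np.argwhere(arr) if arr.dtype == bool else np.atleast_2d(arr)
    if len(vox) == 0:
        raise ConfigError("roi: empty")
    if (vox < 0).any() or (vox >= np.array(grid.shape)).any():
        raise ConfigError("roi: voxel indices outside z map grid")
    return float(z_map.values[vox[:, 0], vox[:, 1], vox[:, 2]].sum())


def _roi_mass(
    studies: list[CoordinateStudy],
    grid: BrainGrid,
    roi_vox: np.ndarray,
    params: ALEParams,
) -> float:
    """ROI mass of the unthresholded z map of an ALE over ``studies``.

    Computes MA maps in full (needed for the null histograms) but
    evaluates ALE, p and z only at the ROI voxels.
    """
    mas = [ma_map(s, grid, params.fwhm_mm, params.trunc_sigma) for s in studies]
    probs = ale_null_distribution(mas, params.bin_width)
    tail = _tail_from_probs(probs)
    acc = np.ones(len(roi_vox))
    for m in mas:
        acc *= 1.0 - m.values[roi_vox[:, 0], roi_vox[:, 1], roi_vox[:, 2]]
    ale_roi = 1.0 - acc
    idx = np.clip(
        np.rint(ale_roi / params.bin_width).astype(np.int64), 0, len(tail) - 1
    )
    p = np.maximum(tail[idx], _P_FLOOR)
    z = np.clip(-ndtri(p), -MAX_Z, MAX_Z)
    return float(z.sum())


def specificity_test(
    matched_studies: list[CoordinateStudy],
    reference_pool: list[CoordinateStudy],
    roi,
    grid: BrainGrid,
    ale_params: ALEParams = ALEParams(),
    n_iter: int = 10_000,
    seed: int = 0,
    exclude_roi_flag: bool = False,
) -> SpecificityResult:
    """Monte-Carlo specificity of ROI activation to the matched literature.

    The observed statistic is the ROI cluster mass of the z map from an
    ALE over ALL matched studies (ROI-table-flagged studies included by
    default, so p-values are indicative when such studies are present;
    ``exclude_roi_flag=True`` drops them). Each iteration draws
    ``len(matched_studies)`` studies without replacement from the
    reference pool and records the same statistic;
    ``p = (1 + #{null >= observed}) / (1 + n_iter)``.
    """
    if exclude_roi_flag:
        matched_studies = [s for s in matched_studies if not s.roi_table_flag]
    if n_iter < 100:
        raise ConfigError("n_iter: must be >= 100")
    if len(reference_pool) < len(matched_studies):
        raise ConfigError(
            f"reference_pool: {len(reference_pool)} studies < "
            f"{len(matched_studies)} matched studies"
        )
    if isinstance(roi, ROI):
        roi_vox, roi_id = roi.voxels, roi.roi_id
    else:
        arr = np.asarray(roi)
        roi_vox = np.argwhere(arr) if arr.dtype == bool else np.atleast_2d(arr)
        roi_id = 0
    if len(roi_vox) == 0:
        raise ConfigError("roi: empty")

    observed = _roi_mass(matched_studies, grid, roi_vox, ale_params)
    rng = np.random.default_rng(seed)
    n_draw = len(matched_studies)
    pool = np.asarray(reference_pool, dtype=object)
    null = np.empty(n_iter)
    for it in range(n_iter):
        pick = rng.choice(len(pool), size=n_draw, replace=False)
        null[it] = _roi_mass(list(pool[pick]), grid, roi_vox, ale_params)
    p = (1.0 + np.count_nonzero(null >= observed)) / (1.0 + n_iter)
    return SpecificityResult(roi_id, observed, null, float(p), n_iter, seed)
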