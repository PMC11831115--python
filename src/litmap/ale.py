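"""Coordinate-based Activation Likelihood Estimation (ALE).

A from-scratch ALE: every study's peak coordinates (foci) are blurred with a
fixed-FWHM isotropic Gaussian probability kernel into a modeled-activation
(MA) map, MA maps are combined across studies as a union of probabilities,
voxel-wise p-values come from an analytic null built by weighted convolution
of the per-study MA histograms (random-spatial-association assumption), and
cluster-level family-wise error is controlled by a Monte-Carlo permutation
of foci locations.

The kernel FWHM is fixed (default 10 mm) for all studies regardless of
sample size; this deliberately differs from sample-size-adaptive ALE
variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.special import ndtri

from .grid import BrainGrid, ConfigError

__all__ = [
    "CoordinateStudy",
    "VoxelMap",
    "ClusterTable",
    "ALEParams",
    "ALEResult",
    "gaussian_kernel_cube",
    "ma_map",
    "ale_combine",
    "ale_null_distribution",
    "ale_null_pmap",
    "relocation_null_pmap",
    "zmap_from_p",
    "cluster_fwe",
    "run_ale",
]

#: z ceiling used when p hits its floor (float64 Phi^-1 territory)
MAX_Z = 38.5
_P_FLOOR = 1e-320

_MNI_TAGS = {"mni", "mni152", "mni152nlin2009casym", "mni152nlin6asym"}


@dataclass(frozen=True)
class CoordinateStudy:
    """One neuroimaging study's reported peak activations.

    ``foci`` are (n, 3) mm coordinates in MNI152-style space.
    ``roi_table_flag`` marks studies whose coordinate tables came from an
    a-priori region-of-interest analysis (a known oversampling bias in
    meta-analysis); such studies can be excluded from ALE runs.
    """

    study_id: str
    foci: np.ndarray
    space: str = "MNI"
    sample_size: int | None = None
    roi_table_flag: bool = False
    tags: frozenset[str] = frozenset()

    def __post_init__(self):
        foci = np.atleast_2d(np.asarray(self.foci, dtype=float))
        if foci.shape[0] < 1 or foci.shape[1] != 3:
            raise ConfigError(f"foci: study {self.study_id} needs >= 1 (x,y,z) focus")
        if not np.all(np.isfinite(foci)):
            raise ConfigError(f"foci: study {self.study_id} has non-finite coordinates")
        object.__setattr__(self, "foci", foci)
        object.__setattr__(self, "tags", frozenset(self.tags))


@dataclass(frozen=True)
class VoxelMap:
    """Values on a :class:`BrainGrid`; ``kind`` tags the semantics."""

    grid: BrainGrid
    values: np.ndarray
    kind: str  # MA | ALE | p | z | overlap | mask

    def __post_init__(self):
        if self.values.shape != tuple(self.grid.shape):
            raise ConfigError("values: shape does not match grid")

    def in_mask(self) -> np.ndarray:
        return self.values[self.grid.mask]


@dataclass
class ClusterInfo:
    cluster_id: int
    voxels: np.ndarray  # (n, 3) integer indices
    extent: int
    mass: float
    peak_mm: np.ndarray
    p_fwe: float
    significant: bool


@dataclass
class ClusterTable:
    """Supra-threshold clusters with permutation-corrected p-values."""

    clusters: list[ClusterInfo]
    alpha: float
    stat: str
    n_perm: int
    null_max_stats: np.ndarray = field(default=None, repr=False)

    def __len__(self):
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def significance_mask(self, grid: BrainGrid) -> np.ndarray:
        out = np.zeros(grid.shape, dtype=bool)
        for c in self.clusters:
            if c.significant:
                out[c.voxels[:, 0], c.voxels[:, 1], c.voxels[:, 2]] = True
        return out


# ---------------------------------------------------------------------------
# kernel


def _fwhm_to_sigma(fwhm_mm: float) -> float:
    return fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def gaussian_kernel_cube(
    fwhm_mm: float, resolution_mm: float, trunc_sigma: float = 3.5
) -> tuple[np.ndarray, int]:
    """Discretized isotropic Gaussian probability kernel.

    Evaluated at voxel-center offsets, truncated at ``trunc_sigma`` standard
    deviations and normalized to unit sum, so a single focus deposits exactly
    one unit of probability mass on the grid. Returns the dense
    ``(2R+1)^3`` cube and its half-width ``R`` in voxels.
    """
    if fwhm_mm <= 0:
        raise ConfigError("fwhm_mm: must be > 0")
    sigma = _fwhm_to_sigma(fwhm_mm)
    radius_mm = trunc_sigma * sigma
    r = int(np.floor(radius_mm / resolution_mm))
    ax = np.arange(-r, r + 1) * resolution_mm
    dx2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    cube = np.exp(-dx2 / (2.0 * sigma**2))
    cube[np.sqrt(dx2) > radius_mm] = 0.0
    cube /= cube.sum()
    return cube, r


# ---------------------------------------------------------------------------
# MA and ALE maps


def _scatter_max(idx: np.ndarray, shape: tuple, cube: np.ndarray, r: int,
                 padded: np.ndarray | None = None) -> np.ndarray:
    """Max-combine kernel cubes centered at voxel indices ``idx`` (n, 3).

    Works on a zero-padded array so kernels may overhang the grid edge;
    returns the cropped (unmasked) MA array.
    """
    pshape = tuple(s + 2 * r for s in shape)
    if padded is None:
        padded = np.zeros(pshape)
    else:
        padded.fill(0.0)
    w = 2 * r + 1
    for i, j, k in idx:
        region = padded[i : i + w, j : j + w, k : k + w]
        np.maximum(region, cube, out=region)
    if r == 0:
        return padded.copy()
    return padded[r:-r, r:-r, r:-r].copy()


def ma_map(study: CoordinateStudy, grid: BrainGrid, fwhm_mm: float = 10.0,
           trunc_sigma: float = 3.5) -> VoxelMap:
    """Modeled-activation map of one study.

    Each focus contributes a discretized Gaussian probability kernel
    (sigma = FWHM / (2*sqrt(2 ln 2))); the study's MA value at a voxel is
    the maximum over its foci's kernel values, so multiple nearby peaks do
    not multiply-count within a study. Foci outside the mask are projected
    to the nearest in-mask voxel with a warning.
    """
    foci = study.foci
    inside = grid.contains_mm(foci)
    if not inside.all():
        n_out = int((~inside).sum())
        warnings.warn(
            f"study {study.study_id}: {n_out} focus/foci outside mask, "
            "projected to nearest in-mask voxel",
            stacklevel=2,
        )
        foci = foci.copy()
        foci[~inside] = grid.nearest_in_mask(foci[~inside])
    idx = grid.mm_to_voxel(foci)
    cube, r = gaussian_kernel_cube(fwhm_mm, _grid_resolution(grid), trunc_sigma)
    values = _scatter_max(idx, grid.shape, cube, r)
    values[~grid.mask] = 0.0
    return VoxelMap(grid, values, "MA")


def _grid_resolution(grid: BrainGrid) -> float:
    sizes = np.sqrt((grid.affine[:3, :3] ** 2).sum(axis=0))
    if not np.allclose(sizes, sizes[0], rtol=1e-6):
        raise ConfigError("affine: anisotropic voxels are not supported")
    return float(sizes[0])


def ale_combine(ma_maps: list[VoxelMap]) -> VoxelMap:
    """Union-of-probabilities combination: ALE = 1 - prod(1 - MA_s)."""
    if not ma_maps:
        raise ConfigError("ma_maps: need >= 1 MA map")
    grid = ma_maps[0].grid
    if len(ma_maps) == 1:  # exact identity, no float round-trip
        return VoxelMap(grid, ma_maps[0].values.copy(), "ALE")
    acc = np.ones(grid.shape)
    for m in ma_maps:
        if m.grid is not grid and (
            m.grid.shape != grid.shape or not np.allclose(m.grid.affine, grid.affine)
        ):
            raise ConfigError("ma_maps: grid mismatch")
        acc *= 1.0 - m.values
    values = 1.0 - acc
    values[~grid.mask] = 0.0
    return VoxelMap(grid, values, "ALE")


# ---------------------------------------------------------------------------
# analytic voxel-wise null ("weighted convolution" of MA histograms)


def ale_null_distribution(ma_maps: list[VoxelMap], bin_width: float = 1e-5) -> np.ndarray:
    """Null ALE distribution under random spatial association of studies.

    Each study contributes the histogram of its in-mask MA values (the
    marginal distribution of that study's MA at a uniformly random in-mask
    voxel). Histograms are combined pairwise under the union formula
    ``1 - (1-a)(1-b)``, with probability mass the product of bin masses,
    re-binned to ``bin_width`` after each step. Returns ``probs`` where
    ``probs[i]`` is the null probability of ALE in bin ``i`` (bin value =
    ``i * bin_width``).
    """
    if bin_width <= 0:
        raise ConfigError("bin_width: must be > 0")
    if not ma_maps:
        raise ConfigError("ma_maps: need >= 1 MA map")

    def hist_of(m: VoxelMap) -> np.ndarray:
        vals = m.in_mask()
        idx = np.rint(vals / bin_width).astype(np.int64)
        return np.bincount(idx) / idx.size

    acc = hist_of(ma_maps[0])
    for m in ma_maps[1:]:
        h = hist_of(m)
        ia = np.flatnonzero(acc)
        ib = np.flatnonzero(h)
        va = ia * bin_width
        vb = ib * bin_width
        combined = 1.0 - np.outer(1.0 - va, 1.0 - vb)
        ic = np.rint(combined / bin_width).astype(np.int64)
        mass = np.outer(acc[ia], h[ib])
        acc = np.bincount(ic.ravel(), weights=mass.ravel())
    return acc


def _tail_from_probs(probs: np.ndarray) -> np.ndarray:
    """Upper-tail P(ALE >= bin i) for each bin i."""
    return np.minimum(np.cumsum(probs[::-1])[::-1], 1.0)


def relocation_null_pmap(
    studies: list[CoordinateStudy],
    ale_map: VoxelMap,
    bin_width: float = 1e-5,
    fwhm_mm: float = 10.0,
    trunc_sigma: float = 3.5,
) -> VoxelMap:
    """Exact per-voxel null under uniform focus relocation.

    The alternative to the pooled-histogram null: for each voxel the exact
    distribution of the ALE statistic when every study's foci are redrawn
    independently and uniformly over in-mask voxel centers — i.e. the same
    null model that the cluster-level Monte-Carlo permutations sample. On
    masks that are small relative to the kernel the pooled-histogram null is
    badly non-stationary near the boundary; this variant has no such
    approximation (at the cost of scaling with mask size, so it is meant for
    desk-scale grids).

    For a study with ``n`` foci, ``P(MA(v) <= w) = F_v(w)^n`` where
    ``F_v(w)`` is the fraction of in-mask focus locations whose kernel value
    at ``v`` is ``<= w``; per-voxel distributions are combined across
    studies under the union formula on a ``bin_width`` lattice.
    """
    if bin_width <= 0:
        raise ConfigError("bin_width: must be > 0")
    if len(studies) < 2:
        raise ConfigError("studies: relocation null needs >= 2 studies")
    grid = ale_map.grid
    cube, _r = gaussian_kernel_cube(fwhm_mm, _grid_resolution(grid), trunc_sigma)
    levels = np.unique(cube[cube > 0])  # ascending positive kernel values
    m = len(levels)
    n_mask = grid.n_voxels

    # counts[j, v]: number of in-mask focus positions giving kernel value
    # levels[j] at voxel v  (convolution of the mask with each level set)
    maskf = grid.mask.astype(float)
    counts = np.empty((m, n_mask))
    for j in range(m):
        ind = (cube == levels[j]).astype(float)
        counts[j] = ndimage.convolve(maskf, ind, mode="constant")[grid.mask]
    counts = np.rint(counts).astype(np.int64).T  # (N, m)

    # voxels with identical count profiles share the same null
    profiles, inverse = np.unique(counts, axis=0, return_inverse=True)
    n_foci = np.array([len(s.foci) for s in studies])

    max_ale = 1.0 - (1.0 - levels[-1]) ** len(studies)
    n_bins = int(np.rint(max_ale / bin_width)) + 2
    support_idx = np.rint(levels / bin_width).astype(np.int64)

    obs_idx = np.rint(ale_map.values[grid.mask] / bin_width).astype(np.int64)
    p_in = np.empty(n_mask)
    for u, prof in enumerate(profiles):
        c0 = n_mask - prof.sum()
        cdf = (c0 + np.cumsum(prof)) / n_mask  # P(K <= levels[j])
        cdf0 = c0 / n_mask
        acc = None
        for n in n_foci:
            cdf_n = cdf**n
            pmf_pos = np.diff(cdf_n, prepend=cdf0**n)
            pmf0 = cdf0**n
            if acc is None:
                acc = np.zeros(n_bins)
                acc[0] = pmf0
                np.add.at(acc, support_idx, pmf_pos)
            else:
                ia = np.flatnonzero(acc)
                va = ia * bin_width
                mass_a = acc[ia]
                # mass at MA = 0 leaves the accumulator unchanged
                new = np.zeros(n_bins)
                new[ia] += mass_a * pmf0
                comb = 1.0 - np.outer(1.0 - va, 1.0 - levels)
                ic = np.rint(comb / bin_width).astype(np.int64)
                np.add.at(new, ic.ravel(), np.outer(mass_a, pmf_pos).ravel())
                acc = new
        tail = _tail_from_probs(acc)
        sel = inverse == u
        p_in[sel] = tail[np.clip(obs_idx[sel], 0, n_bins - 1)]

    p = np.ones(grid.shape)
    p[grid.mask] = np.maximum(p_in, _P_FLOOR)
    return VoxelMap(grid, p, "p")


def ale_null_pmap(
    ma_maps: list[VoxelMap],
    bin_width: float = 1e-5,
    ale_map: VoxelMap | None = None,
    method: str = "histogram",
    studies: list[CoordinateStudy] | None = None,
    fwhm_mm: float = 10.0,
    trunc_sigma: float = 3.5,
) -> VoxelMap:
    """Voxel-wise p-map: upper-tail null probability at the observed ALE.

    ``p(v) = P(ALE_null >= ALE_obs(v))``. Two null models are available:

    * ``method="histogram"`` (default, the classic analytic null): pooled
      per-study MA histograms combined by weighted convolution
      (:func:`ale_null_distribution`). Assumes the MA marginal is the same
      at every voxel, which holds away from the mask boundary; on masks
      comparable in size to the kernel it is badly biased near edges.
    * ``method="relocation"``: exact per-voxel null under uniform focus
      relocation (:func:`relocation_null_pmap`); requires ``studies`` and
      is intended for small grids.

    p is floored at the smallest positive double so that the z transform
    stays finite. Outside the mask p = 1.
    """
    if len(ma_maps) < 2:
        raise ConfigError("ma_maps: analytic null needs >= 2 studies")
    if ale_map is None:
        ale_map = ale_combine(ma_maps)
    if method == "relocation":
        if studies is None:
            raise ConfigError("studies: required for method='relocation'")
        return relocation_null_pmap(studies, ale_map, bin_width, fwhm_mm, trunc_sigma)
    if method != "histogram":
        raise ConfigError(f"method: unknown null method {method!r}")
    probs = ale_null_distribution(ma_maps, bin_width)
    tail = _tail_from_probs(probs)
    idx = np.rint(ale_map.values / bin_width).astype(np.int64)
    idx = np.clip(idx, 0, len(tail) - 1)
    p = np.maximum(tail[idx], _P_FLOOR)
    p[~ale_map.grid.mask] = 1.0
    return VoxelMap(ale_map.grid, p, "p")


def zmap_from_p(p_map: VoxelMap, max_z: float = MAX_Z) -> VoxelMap:
    """Standard-normal upper-tail transform z = Phi^-1(1 - p), clipped."""
    with np.errstate(divide="ignore"):
        z = -ndtri(p_map.values)
    z = np.clip(z, -max_z, max_z)
    z[~p_map.grid.mask] = 0.0
    return VoxelMap(p_map.grid, z, "z")


# ---------------------------------------------------------------------------
# cluster-level FWE by Monte-Carlo permutation


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ConfigError("connectivity: must be 6 or 26")


def cluster_fwe(
    ale_map: VoxelMap,
    p_map: VoxelMap,
    studies: list[CoordinateStudy],
    *,
    null_probs: np.ndarray,
    bin_width: float = 1e-5,
    cluster_forming_p: float = 0.001,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    stat: str = "extent",
    fwhm_mm: float = 10.0,
    trunc_sigma: float = 3.5,
    connectivity: int = 26,
) -> ClusterTable:
    """Cluster-level family-wise-error inference by focus permutation.

    Supra-threshold voxels (voxel p < ``cluster_forming_p``) are grouped by
    26-connectivity (default). The cluster-forming p cutoff is converted to
    an ALE-value threshold via the analytic null; each of ``n_perm``
    permutations redraws every study's foci uniformly over in-mask voxel
    centers (focus count preserved per study), recomputes the ALE map,
    re-applies the same threshold and records the maximum cluster statistic
    (``extent`` = voxel count, ``mass`` = sum of z). Cluster
    ``p_fwe = (1 + #{perm max >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ConfigError("n_perm: must be >= 100")
    if stat not in ("extent", "mass"):
        raise ConfigError("stat: must be 'extent' or 'mass'")
    grid = ale_map.grid
    structure = _connectivity_structure(connectivity)

    tail = _tail_from_probs(null_probs)
    below = np.flatnonzero(tail < cluster_forming_p)
    rng = np.random.default_rng(seed)

    if below.size == 0:
        # no attainable ALE value crosses the cluster-forming threshold
        return ClusterTable([], alpha, stat, n_perm, np.zeros(n_perm))
    idx_thresh = int(below[0])

    # z value per ALE bin, for the mass statistic
    with np.errstate(divide="ignore"):
        z_of_bin = np.clip(-ndtri(np.maximum(tail, _P_FLOOR)), -MAX_Z, MAX_Z)

    def binned(values: np.ndarray) -> np.ndarray:
        idx = np.rint(values / bin_width).astype(np.int64)
        return np.clip(idx, 0, len(tail) - 1)

    def cluster_stats(supra: np.ndarray, bins: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        labels, n = ndimage.label(supra, structure=structure)
        if n == 0:
            return labels, np.zeros(0)
        if stat == "extent":
            stats = ndimage.sum_labels(supra, labels, index=np.arange(1, n + 1))
        else:
            stats = ndimage.sum_labels(z_of_bin[bins], labels, index=np.arange(1, n + 1))
        return labels, np.asarray(stats, dtype=float)

    obs_bins = binned(ale_map.values)
    obs_supra = (obs_bins >= idx_thresh) & grid.mask
    obs_labels, obs_stats = cluster_stats(obs_supra, obs_bins)

    # permutation null of the maximum cluster statistic
    mask_idx = grid.mask_indices
    n_mask = len(mask_idx)
    cube, r = gaussian_kernel_cube(fwhm_mm, _grid_resolution(grid), trunc_sigma)
    pshape = tuple(s + 2 * r for s in grid.shape)
    padded = np.zeros(pshape)
    n_foci = [len(s.foci) for s in studies]
    max_stats = np.zeros(n_perm)
    for it in range(n_perm):
        acc = np.ones(grid.shape)
        for nf in n_foci:
            draw = mask_idx[rng.integers(0, n_mask, size=nf)]
            ma = _scatter_max(draw, grid.shape, cube, r, padded=padded)
            acc *= 1.0 - ma
        ale = 1.0 - acc
        bins = binned(ale)
        supra = (bins >= idx_thresh) & grid.mask
        if supra.any():
            _, stats = cluster_stats(supra, bins)
            if stats.size:
                max_stats[it] = stats.max()

    clusters: list[ClusterInfo] = []
    order = np.argsort(-obs_stats)
    for new_id, ci in enumerate(order, start=1):
        sel = np.argwhere(obs_labels == ci + 1)
        s = obs_stats[ci]
        p_fwe = (1.0 + np.count_nonzero(max_stats >= s)) / (1.0 + n_perm)
        vals = ale_map.values[sel[:, 0], sel[:, 1], sel[:, 2]]
        peak = sel[np.argmax(vals)]
        clusters.append(
            ClusterInfo(
                cluster_id=new_id,
                voxels=sel,
                extent=len(sel),
                mass=float(ndimage.sum_labels(z_of_bin[obs_bins], obs_labels, index=ci + 1)),
                peak_mm=ale_map.grid.voxel_to_mm(peak)[0],
                p_fwe=float(p_fwe),
                significant=bool(p_fwe < alpha),
            )
        )
    return ClusterTable(clusters, alpha, stat, n_perm, max_stats)


# ---------------------------------------------------------------------------
# one-call ALE analysis


@dataclass(frozen=True)
class ALEParams:
    """Parameters of a full ALE analysis.

    Defaults mirror common coordinate-based meta-analysis practice: 10 mm
    FWHM kernel for every study, cluster-forming voxel p < 0.001, cluster
    FWE alpha 0.05 with Monte-Carlo permutations.
    """

    fwhm_mm: float = 10.0
    trunc_sigma: float = 3.5
    bin_width: float = 1e-5
    cluster_forming_p: float = 0.001
    alpha: float = 0.05
    n_perm: int = 1000
    stat: str = "extent"
    connectivity: int = 26
    min_studies: int = 2
    seed: int = 0
    allow_nonmni: bool = False
    exclude_roi_flagged: bool = False


@dataclass
class ALEResult:
    ale: VoxelMap
    p: VoxelMap
    z: VoxelMap
    clusters: ClusterTable
    sig_mask: np.ndarray
    n_studies: int


def _check_spaces(studies: list[CoordinateStudy], allow_nonmni: bool) -> None:
    for s in studies:
        if s.space.lower().replace("-", "").replace("_", "") not in _MNI_TAGS:
            if not allow_nonmni:
                raise ConfigError(
                    f"space: study {s.study_id} reports space {s.space!r}; "
                    "only MNI152-style coordinates are supported "
                    "(set allow_nonmni to override)"
                )


def run_ale(studies: list[CoordinateStudy], grid: BrainGrid,
            params: ALEParams = ALEParams()) -> ALEResult:
    """Full single-group ALE: MA maps -> ALE -> analytic p/z -> cluster FWE."""
    if params.exclude_roi_flagged:
        studies = [s for s in studies if not s.roi_table_flag]
    if len(studies) < max(params.min_studies, 2):
        raise ConfigError(
            f"studies: need >= {max(params.min_studies, 2)} studies, got {len(studies)}"
        )
    _check_spaces(studies, params.allow_nonmni)
    mas = [ma_map(s, grid, params.fwhm_mm, params.trunc_sigma) for s in studies]
    ale = ale_combine(mas)
    null_probs = ale_null_distribution(mas, params.bin_width)
    tail = _tail_from_probs(null_probs)
    idx = np.clip(
        np.rint(ale.values / params.bin_width).astype(np.int64), 0, len(tail) - 1
    )
    p = VoxelMap(grid, np.where(grid.mask, np.maximum(tail[idx], _P_FLOOR), 1.0), "p")
    z = zmap_from_p(p)
    clusters = cluster_fwe(
        ale,
        p,
        studies,
        null_probs=null_probs,
        bin_width=params.bin_width,
        cluster_forming_p=params.cluster_forming_p,
        alpha=params.alpha,
        n_perm=params.n_perm,
        seed=params.seed,
        stat=params.stat,
        fwhm_mm=params.fwhm_mm,
        trunc_sigma=params.trunc_sigma,
        connectivity=params.connectivity,
    )
    sig = clusters.significance_mask(grid)
    return ALEResult(ale, p, z, clusters, sig, len(studies))
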