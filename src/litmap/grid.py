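"""Voxel grids, affines and brain masks.

All public coordinates are millimetres in an MNI152-style RAS+ convention;
voxel indices appear only inside this package. Synthetic analyses run on an
analytic ellipsoid (or box) mask so that no reference template needs to be
downloaded; real masks can be loaded from NIfTI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree


class ConfigError(ValueError):
    """A configuration value is invalid; the message names the field."""


@dataclass(frozen=True)
class BrainGrid:
    """A 3-D voxel grid with an affine and a boolean brain mask.

    Parameters
    ----------
    shape : tuple of int
        Array shape (nx, ny, nz).
    affine : (4, 4) ndarray
        Voxel-index -> mm homogeneous transform; must be invertible.
    mask : ndarray of bool
        In-brain voxels; must be nonempty.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    mask: np.ndarray
    _kdtree: cKDTree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.mask.shape != tuple(self.shape):
            raise ConfigError("mask: shape does not match grid shape")
        if not self.mask.any():
            raise ConfigError("mask: empty mask")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ConfigError("affine: not invertible")

    # -- coordinate transforms -------------------------------------------
    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Voxel indices (…, 3) to mm coordinates of voxel centers."""
        ijk = np.atleast_2d(ijk)
        out = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out

    def mm_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """mm coordinates (…, 3) to nearest voxel indices (rounded)."""
        xyz = np.atleast_2d(xyz)
        inv = np.linalg.inv(self.affine)
        ijk = xyz @ inv[:3, :3].T + inv[:3, 3]
        return np.rint(ijk).astype(np.int64)

    # -- mask helpers ----------------------------------------------------
    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def mask_indices(self) -> np.ndarray:
        """(N, 3) integer indices of in-mask voxels, C-order."""
        return np.argwhere(self.mask)

    @property
    def mask_coords_mm(self) -> np.ndarray:
        """(N, 3) mm centers of in-mask voxels."""
        return self.voxel_to_mm(self.mask_indices)

    def contains_mm(self, xyz: np.ndarray) -> np.ndarray:
        """Whether each mm point falls on an in-mask voxel."""
        ijk = self.mm_to_voxel(xyz)
        ok = np.all((ijk >= 0) & (ijk < np.array(self.shape)), axis=1)
        out = np.zeros(len(ijk), dtype=bool)
        if ok.any():
            sel = ijk[ok]
            out[ok] = self.mask[sel[:, 0], sel[:, 1], sel[:, 2]]
        return out

    def nearest_in_mask(self, xyz: np.ndarray) -> np.ndarray:
        """Project mm points onto the nearest in-mask voxel center (mm)."""
        tree = self._tree()
        _, idx = tree.query(np.atleast_2d(xyz))
        return self.mask_coords_mm[idx]

    def _tree(self) -> cKDTree:
        if self._kdtree is None:
            object.__setattr__(self, "_kdtree", cKDTree(self.mask_coords_mm))
        return self._kdtree


@dataclass(frozen=True)
class GridSpec:
    """Serializable recipe for a :class:`BrainGrid` (see :func:`make_grid`)."""

    resolution_mm: float = 4.0
    mask_source: str = "ellipsoid"
    semi_axes_mm: tuple[float, float, float] = (66.0, 80.0, 66.0)
    box_shape: tuple[int, int, int] | None = None
    nifti_path: str | None = None

    def make(self) -> "BrainGrid":
        return make_grid(
            self.resolution_mm,
            mask_source=self.mask_source,
            semi_axes_mm=tuple(self.semi_axes_mm),
            box_shape=tuple(self.box_shape) if self.box_shape else None,
            nifti_path=self.nifti_path,
        )


def make_grid(
    resolution_mm: float,
    mask_source: str = "ellipsoid",
    semi_axes_mm: tuple[float, float, float] = (66.0, 80.0, 66.0),
    box_shape: tuple[int, int, int] | None = None,
    nifti_path: str | None = None,
) -> BrainGrid:
    """Build a :class:`BrainGrid` at an isotropic resolution.

    ``mask_source`` is one of:

    * ``"ellipsoid"`` — analytic ellipsoid with the given mm semi-axes,
      centered at mm origin (default axes roughly brain-sized);
    * ``"box"`` — full-cuboid mask of ``box_shape`` voxels, centered at
      mm origin (used for small exact test fixtures);
    * ``"nifti"`` — load mask (values > 0) and affine from ``nifti_path``.
    """
    if resolution_mm <= 0:
        raise ConfigError("resolution_mm: must be > 0")
    res = float(resolution_mm)

    if mask_source == "nifti":
        import nibabel as nib

        img = nib.load(nifti_path)
        mask = np.asarray(img.get_fdata()) > 0
        if not mask.any():
            raise ConfigError("mask_source: empty mask in NIfTI file")
        return BrainGrid(tuple(mask.shape), np.asarray(img.affine, dtype=float), mask)

    if mask_source == "box":
        if box_shape is None:
            raise ConfigError("box_shape: required for mask_source='box'")
        shape = tuple(int(s) for s in box_shape)
        mask = np.ones(shape, dtype=bool)
    elif mask_source == "ellipsoid":
        a, b, c = (float(s) for s in semi_axes_mm)
        if min(a, b, c) <= 0:
            raise ConfigError("semi_axes_mm: must be > 0")
        shape = tuple(2 * int(np.floor(s / res)) + 1 for s in (a, b, c))
        mask = None
    else:
        raise ConfigError(f"mask_source: unknown value {mask_source!r}")

    # RAS+ affine with the grid centered on the mm origin
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = res
    center = (np.array(shape) - 1) / 2.0
    affine[:3, 3] = -center * res

    if mask is None:
        idx = np.indices(shape).reshape(3, -1).T
        xyz = idx * res + affine[:3, 3]
        a, b, c = (float(s) for s in semi_axes_mm)
        mask = ((xyz[:, 0] / a) ** 2 + (xyz[:, 1] / b) ** 2 + (xyz[:, 2] / c) ** 2) <= 1.0
        mask = mask.reshape(shape)
        if not mask.any():
            raise ConfigError("semi_axes_mm: ellipsoid contains no voxel centers")

    return BrainGrid(shape, affine, mask)
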