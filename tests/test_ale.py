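import numpy as np
import pytest
from hypothesis import given, strategies as st

from litmap.ale import (
    ALEParams,
    CoordinateStudy,
    VoxelMap,
    ale_combine,
    ale_null_pmap,
    cluster_fwe,
    ale_null_distribution,
    gaussian_kernel_cube,
    ma_map,
    run_ale,
    zmap_from_p,
)
from litmap.grid import ConfigError, make_grid
from litmap.synthetic import CoordConfig, generate_coordinate_studies


def _study(foci, sid="s", **kw):
    return CoordinateStudy(sid, np.atleast_2d(foci), **kw)


# ---------------------------------------------------------------------------
# kernel and MA maps


def test_kernel_matches_dense_gaussian_oracle():
    """Independent recount: evaluate the truncated Gaussian density on the
    voxel-center lattice with explicit loops and renormalize."""
    fwhm, res, trunc = 10.0, 4.0, 3.5
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
    r = int(np.floor(trunc * sigma / res))
    vals = {}
    total = 0.0
    for i in range(-r, r + 1):
        for j in range(-r, r + 1):
            for k in range(-r, r + 1):
                d = res * np.sqrt(i * i + j * j + k * k)
                w = np.exp(-(d**2) / (2 * sigma**2)) if d <= trunc * sigma else 0.0
                vals[(i, j, k)] = w
                total += w
    cube, r_got = gaussian_kernel_cube(fwhm, res, trunc)
    assert r_got == r
    for (i, j, k), w in vals.items():
        assert cube[i + r, j + r, k + r] == pytest.approx(w / total)
    assert cube.sum() == pytest.approx(1.0)


def test_ma_peak_at_focus_with_kernel_center_weight(box_grid):
    cube, _ = gaussian_kernel_cube(10.0, 4.0)
    ma = ma_map(_study([2.0, 2.0, 2.0]), box_grid)  # exactly on a voxel center
    peak_idx = np.unravel_index(np.argmax(ma.values), ma.values.shape)
    assert box_grid.voxel_to_mm(np.array([peak_idx]))[0] == pytest.approx([2.0, 2.0, 2.0])
    assert ma.values.max() == pytest.approx(cube.max())
    assert (ma.values >= 0).all() and (ma.values <= 1).all()


def test_coincident_foci_equal_single_focus(box_grid):
    one = ma_map(_study([2.0, 2.0, 2.0]), box_grid)
    two = ma_map(_study([[2.0, 2.0, 2.0], [2.0, 2.0, 2.0]]), box_grid)
    assert np.array_equal(one.values, two.values)


def test_out_of_mask_focus_projected_with_warning(box_grid):
    with pytest.warns(UserWarning, match="projected"):
        ma = ma_map(_study([999.0, 0.0, 0.0]), box_grid)
    assert ma.values.max() > 0


# ---------------------------------------------------------------------------
# ALE combination


def test_union_identity_hand_values(box_grid):
    a = VoxelMap(box_grid, np.full(box_grid.shape, 0.2), "MA")
    b = VoxelMap(box_grid, np.full(box_grid.shape, 0.5), "MA")
    ale = ale_combine([a, b])
    assert ale.values[box_grid.mask] == pytest.approx(0.6)


def test_single_study_identity_and_union_bound(box_grid):
    ma = ma_map(_study([2.0, -2.0, 2.0]), box_grid)
    assert np.array_equal(ale_combine([ma]).values, ma.values)
    ma2 = ma_map(_study([-6.0, 6.0, -6.0], "s2"), box_grid)
    ale = ale_combine([ma, ma2])
    assert (ale.values >= np.maximum(ma.values, ma2.values) - 1e-15).all()


def test_zero_ma_study_changes_nothing(box_grid):
    ma = ma_map(_study([2.0, 2.0, 2.0]), box_grid)
    zero = VoxelMap(box_grid, np.zeros(box_grid.shape), "MA")
    # up to one float round-trip through 1 - (1 - x)
    assert np.allclose(ale_combine([ma, zero]).values, ma.values, rtol=0, atol=1e-15)


def test_grid_mismatch_rejected(box_grid):
    other = make_grid(4.0, mask_source="box", box_shape=(5, 5, 5))
    with pytest.raises(ConfigError, match="grid"):
        ale_combine([
            VoxelMap(box_grid, np.zeros(box_grid.shape), "MA"),
            VoxelMap(other, np.zeros(other.shape), "MA"),
        ])


@given(st.lists(st.floats(0.0, 0.99), min_size=2, max_size=5))
def test_ale_monotone_in_each_ma(vals):
    grid = make_grid(4.0, mask_source="box", box_shape=(2, 2, 2))
    maps = [VoxelMap(grid, np.full(grid.shape, v), "MA") for v in vals]
    base = ale_combine(maps).values[0, 0, 0]
    bumped = [VoxelMap(grid, np.full(grid.shape, min(v + 0.005, 1.0)), "MA") for v in vals]
    assert ale_combine(bumped).values[0, 0, 0] >= base


# ---------------------------------------------------------------------------
# analytic null and z transform


def test_null_p_is_one_at_zero_ale(box_grid):
    mas = [ma_map(_study([2.0, 2.0, 2.0], f"s{i}"), box_grid) for i in range(2)]
    p = ale_null_pmap(mas, 1e-5)
    far = box_grid.mm_to_voxel(np.array([[-10.0, -10.0, -10.0]]))[0]
    assert mas[0].values[tuple(far)] == 0.0
    assert p.values[tuple(far)] == 1.0


def test_null_smallest_p_where_all_studies_peak(box_grid):
    mas = [ma_map(_study([2.0, 2.0, 2.0], f"s{i}"), box_grid) for i in range(3)]
    p = ale_null_pmap(mas, 1e-5)
    peak = tuple(box_grid.mm_to_voxel(np.array([[2.0, 2.0, 2.0]]))[0])
    assert p.values[peak] == p.values[box_grid.mask].min()


def test_null_requires_two_studies(box_grid):
    ma = ma_map(_study([0.0, 0.0, 0.0]), box_grid)
    with pytest.raises(ConfigError):
        ale_null_pmap([ma])
    with pytest.raises(ConfigError, match="bin_width"):
        ale_null_distribution([ma, ma], bin_width=0.0)


def test_zmap_standard_normal_quantiles(box_grid):
    vals = np.full(box_grid.shape, 0.5)
    vals[0, 0, 0] = 0.0228
    vals[0, 0, 1] = 0.9772
    z = zmap_from_p(VoxelMap(box_grid, vals, "p"))
    assert z.values[1, 1, 1] == pytest.approx(0.0)
    assert z.values[0, 0, 0] == pytest.approx(2.0, abs=5e-3)
    assert z.values[0, 0, 1] == pytest.approx(-2.0, abs=5e-3)
    # monotone: smaller p => larger z
    ps = np.sort(np.unique(vals))
    zs = [z.values[tuple(np.argwhere(vals == p)[0])] for p in ps]
    assert all(a > b for a, b in zip(zs, zs[1:]))


# ---------------------------------------------------------------------------
# cluster-level FWE


def _null_inputs(studies, grid, bin_width=1e-4):
    mas = [ma_map(s, grid) for s in studies]
    ale = ale_combine(mas)
    probs = ale_null_distribution(mas, bin_width)
    p = ale_null_pmap(mas, bin_width, ale_map=ale)
    return ale, p, probs


def test_planted_locus_yields_significant_cluster(small_grid):
    # 20 studies with foci jittered (sd 4 mm) around a planted origin locus
    rng = np.random.default_rng(3)
    studies = []
    for i in range(20):
        nf = rng.integers(2, 6)
        foci = rng.normal(0.0, 4.0, size=(nf, 3))
        studies.append(_study(foci, f"s{i}"))
    ale, p, probs = _null_inputs(studies, small_grid)
    table = cluster_fwe(ale, p, studies, null_probs=probs, bin_width=1e-4,
                        n_perm=200, seed=0)
    sig = [c for c in table if c.significant]
    assert sig
    locus_vox = tuple(small_grid.mm_to_voxel(np.zeros((1, 3)))[0])
    assert any(tuple(v) == locus_vox for c in sig for v in c.voxels)


def test_cluster_fwe_deterministic(small_grid):
    rng = np.random.default_rng(5)
    studies = [_study(rng.normal(0, 5, size=(3, 3)), f"s{i}") for i in range(10)]
    ale, p, probs = _null_inputs(studies, small_grid)
    t1 = cluster_fwe(ale, p, studies, null_probs=probs, bin_width=1e-4, n_perm=150, seed=9)
    t2 = cluster_fwe(ale, p, studies, null_probs=probs, bin_width=1e-4, n_perm=150, seed=9)
    assert [(c.extent, c.p_fwe) for c in t1] == [(c.extent, c.p_fwe) for c in t2]


def test_single_voxel_mask_degenerate_null():
    """With one in-mask voxel the permutation cannot move foci, the null is
    degenerate, and every cluster gets p_fwe = 1."""
    grid = make_grid(4.0, mask_source="box", box_shape=(1, 1, 1))
    studies = [_study([0.0, 0.0, 0.0], f"s{i}") for i in range(2)]
    ale, p, probs = _null_inputs(studies, grid, bin_width=1e-5)
    # force a supra-threshold cluster despite the degenerate null
    table = cluster_fwe(ale, p, studies, null_probs=probs, bin_width=1e-5,
                        cluster_forming_p=1.1, n_perm=100, seed=0)
    assert len(table) == 1
    assert table.clusters[0].p_fwe == 1.0


def test_no_supra_threshold_voxels_empty_table(small_grid):
    rng = np.random.default_rng(0)
    coords = small_grid.mask_coords_mm
    studies = [_study(coords[rng.integers(0, len(coords), 3)], f"s{i}") for i in range(3)]
    ale, p, probs = _null_inputs(studies, small_grid)
    table = cluster_fwe(ale, p, studies, null_probs=probs, bin_width=1e-4,
                        cluster_forming_p=1e-12, n_perm=100, seed=0)
    assert len(table) == 0


# ---------------------------------------------------------------------------
# run_ale composition


def test_run_ale_rejects_too_few_studies(small_grid):
    with pytest.raises(ConfigError, match="studies"):
        run_ale([], small_grid)
    with pytest.raises(ConfigError, match="studies"):
        run_ale([_study([0.0, 0.0, 0.0])], small_grid)


def test_run_ale_space_validation(small_grid):
    studies = [_study([0.0, 0.0, 0.0], f"s{i}", space="Talairach") for i in range(2)]
    with pytest.raises(ConfigError, match="space"):
        run_ale(studies, small_grid, ALEParams(n_perm=100))


def test_run_ale_roi_flag_exclusion_shrinks_input(small_grid):
    rng = np.random.default_rng(1)
    studies = [_study(rng.normal(0, 5, (3, 3)), f"s{i}", roi_table_flag=(i < 3))
               for i in range(10)]
    keep = run_ale(studies, small_grid, ALEParams(n_perm=100, seed=1))
    drop = run_ale(studies, small_grid,
                   ALEParams(n_perm=100, seed=1, exclude_roi_flagged=True))
    assert drop.n_studies == 7 < keep.n_studies == 10
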