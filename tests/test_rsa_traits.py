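import warnings

import numpy as np
import pytest

from oracles import (
    ABOVE,
    BELOW,
    OUTSIDE,
    box_label,
    grid_code,
    grid_label,
    layer_label,
    mc_hull_volume,
    partition_oracle,
)
from vinearch.core import SegmentList
from vinearch.rsa_traits import (
    DEFAULT_BOX,
    GridSpec,
    SoilLayerProfile,
    aspect_ratio,
    compute_rsa_traits,
    convex_hulls,
    dbi,
    grid_root_length,
    max_horizontal_spread,
    max_rooting_depth,
    outside_fraction,
    root_length_by_layer,
    total_root_length,
)
from vinearch.synthetic import make_fixture

from conftest import random_segments


def seg(*pairs):
    pairs = np.asarray(pairs, dtype=float)
    return SegmentList(pairs[:, 0], pairs[:, 1])


# ---------------------------------------------------------------------------
# total length / depth / spread

def test_total_length_345_triangle():
    assert total_root_length(seg([(0, 0, 0), (3, 4, 0)])) == pytest.approx(5.0)


def test_total_length_collinear_segments():
    s = seg([(0, 0, 0), (0, 0, -50)], [(0, 0, -50), (0, 0, -100)])
    assert total_root_length(s) == pytest.approx(100.0)


def test_total_length_empty():
    assert total_root_length(SegmentList(np.empty((0, 3)), np.empty((0, 3)))) == 0.0


def test_max_depth_from_surface():
    s = seg([(0, 0, -5), (0, 0, -185)])
    assert max_rooting_depth(s, soil_surface_z=-5) == pytest.approx(180.0)


def test_surface_horizontal_root_zero_depth():
    s = seg([(0, 0, -5), (30, 0, -5)])
    assert max_rooting_depth(s, soil_surface_z=-5) == 0.0


def test_all_above_surface_warns():
    s = seg([(0, 0, 10), (0, 0, 20)])
    with pytest.warns(UserWarning, match="above the soil surface"):
        assert max_rooting_depth(s, soil_surface_z=-5) == 0.0


def test_spread_ignores_z():
    s = seg([(0, 0, -10), (80, 0, -90)])
    assert max_horizontal_spread(s) == pytest.approx(80.0)


def test_spread_degenerate_xy():
    s = seg([(3, 4, 0), (3, 4, -50)])
    assert max_horizontal_spread(s) == 0.0


def test_spread_matches_bruteforce(rng):
    s = random_segments(rng, n_roots=10, n_points=26)  # 500 points
    pts = s.points[:, :2]
    diff = pts[:, None, :] - pts[None, :, :]
    brute = np.sqrt((diff ** 2).sum(-1)).max()
    assert max_horizontal_spread(s) == pytest.approx(brute, rel=1e-12)


def test_spread_radial_mode():
    s = seg([(0, 0, -10), (30, 0, -10)])
    assert max_horizontal_spread(s, mode="radial") == pytest.approx(60.0)


# ---------------------------------------------------------------------------
# hulls and aspect ratio

def test_cube_hull_volume_1dm3():
    h = convex_hulls(make_fixture("cube_cloud_10cm").segments())
    assert h.volume3d == pytest.approx(1.0)
    assert h.area_xy == pytest.approx(1.0)


def test_tetrahedron_volume():
    s = seg([(0, 0, 0), (10, 0, 0)], [(0, 0, 0), (0, 10, 0)], [(0, 0, 0), (0, 0, 10)])
    h = convex_hulls(s)
    assert h.volume3d * 1000 == pytest.approx(1000.0 / 6.0)


def test_degenerate_hull_flags():
    h = convex_hulls(make_fixture("straight_vertical_100").segments())
    assert h.degenerate3d and h.volume3d == 0.0


def test_hull_matches_monte_carlo(rng):
    s = random_segments(rng, n_roots=8, n_points=10)
    h = convex_hulls(s)
    mc_vol = mc_hull_volume(np.unique(s.points, axis=0), n=1_000_000, seed=1)
    assert h.volume3d * 1000 == pytest.approx(mc_vol, rel=0.02)
    mc_area = mc_hull_volume(np.unique(s.points[:, :2], axis=0), n=1_000_000, seed=2)
    assert h.area_xy * 100 == pytest.approx(mc_area, rel=0.02)


@pytest.mark.parametrize("dx,dy,expected", [(100, 100, 1.0), (200, 100, 2.0),
                                            (50, 150, 1.0 / 3.0)])
def test_aspect_ratio_from_extents(dx, dy, expected):
    s = seg([(0, 0, -10), (dx, dy, -10)], [(0, dy, -10), (dx, 0, -10)])
    assert aspect_ratio(convex_hulls(s)) == pytest.approx(expected)


def test_aspect_ratio_zero_y_extent_warns_nan():
    h = convex_hulls(seg([(0, 0, -10), (100, 0, -10)]))
    with pytest.warns(UserWarning, match="aspect ratio"):
        assert np.isnan(aspect_ratio(h))


# ---------------------------------------------------------------------------
# layer partitioning

def test_vertical_segment_layers():
    s = seg([(0, 0, -5), (0, 0, -105)])  # depth 0 to 100 under surface -5
    ll = root_length_by_layer(s, SoilLayerProfile((0, 30, 60, 90, 120)),
                              soil_surface_z=-5)
    np.testing.assert_allclose(ll.lengths, [30, 30, 30, 10])
    assert ll.above == 0 and ll.below == 0


def test_segment_inside_single_layer():
    s = seg([(0, 0, -40), (25, 0, -45)])
    ll = root_length_by_layer(s, SoilLayerProfile((0, 30, 60, 90)), soil_surface_z=-5)
    assert ll.lengths[1] == pytest.approx(s.lengths.sum())
    assert ll.lengths[[0, 2]].sum() == 0


def test_oblique_345_split_at_boundary():
    # 3-4-5 segment, depth 28.5 -> 31.5: the 30-cm boundary is crossed at
    # the vertical midpoint, so 2.5 cm of the 5-cm length falls in each layer
    s = seg([(0, 0, -33.5), (4, 0, -36.5)])
    ll = root_length_by_layer(s, SoilLayerProfile((0, 30, 60)), soil_surface_z=-5)
    np.testing.assert_allclose(ll.lengths, [2.5, 2.5])


def test_equal_mode_splits_among_touched_layers():
    s = seg([(0, 0, -5), (0, 0, -105)])
    ll = root_length_by_layer(s, SoilLayerProfile((0, 30, 60, 90, 120)),
                              soil_surface_z=-5, mode="equal")
    np.testing.assert_allclose(ll.lengths, [25, 25, 25, 25])


def test_above_surface_bucket():
    s = seg([(0, 0, 5), (0, 0, -15)])  # depth -10 to 10 around surface -5
    ll = root_length_by_layer(s, SoilLayerProfile((0, 30)), soil_surface_z=-5)
    assert ll.above == pytest.approx(10.0)
    assert ll.lengths[0] == pytest.approx(10.0)


def test_layer_allocation_matches_subdivision_oracle(rng):
    profile = SoilLayerProfile((0, 30, 60, 90, 120, 150, 210))
    s = random_segments(rng, n_roots=6, n_points=7, scale=120, z_offset=-80)
    ll = root_length_by_layer(s, profile, soil_surface_z=-5)
    oracle = partition_oracle(s, layer_label(-5, profile.boundaries))
    total = s.lengths.sum()
    for i in range(profile.n_layers):
        assert abs(ll.lengths[i] - oracle.get(i, 0.0)) < 1e-6 * total
    assert abs(ll.above - oracle.get(ABOVE, 0.0)) < 1e-6 * total
    assert abs(ll.below - oracle.get(BELOW, 0.0)) < 1e-6 * total


# ---------------------------------------------------------------------------
# grid and DBI

def test_segment_inside_one_cell():
    g = grid_root_length(seg([(1, 1, -10), (8, 8, -10)]), GridSpec(cell=10))
    assert set(g.cell_lengths) == {(0, 0)}
    assert g.normalized[(0, 0)] == pytest.approx(1.0)


def test_symmetric_two_cell_crossing():
    g = grid_root_length(seg([(5, 2, -10), (15, 2, -10)]), GridSpec(cell=10))
    assert g.cell_lengths[(0, 0)] == pytest.approx(5.0)
    assert g.cell_lengths[(1, 0)] == pytest.approx(5.0)


def test_vertical_segment_full_length_in_one_cell():
    g = grid_root_length(seg([(3, 4, -10), (3, 4, -110)]), GridSpec(cell=10))
    assert g.cell_lengths[(0, 0)] == pytest.approx(100.0)


def test_grid_allocation_matches_subdivision_oracle(rng):
    s = random_segments(rng, n_roots=5, n_points=6, scale=90)
    g = grid_root_length(s, GridSpec(cell=10))
    oracle = partition_oracle(s, grid_label(10.0))
    total = s.lengths.sum()
    assert sum(oracle.values()) == pytest.approx(total)
    for (i, j), v in g.cell_lengths.items():
        assert abs(v - oracle.pop(grid_code(i, j), 0.0)) < 1e-6 * total
    assert all(v < 1e-6 * total for v in oracle.values())


def test_dbi_row_aligned_is_minus_one():
    g = grid_root_length(seg([(0, 10, -10), (0, 130, -10)]), GridSpec(cell=10))
    assert dbi(g) == pytest.approx(-1.0)


def test_dbi_30_10_gives_half():
    # inter-row arm 30 cm, row arm 10 cm, both clear of |x| = |y| tie cells
    s = seg([(10, 0, -10), (40, 0, -10)], [(0, 10, -10), (0, 20, -10)])
    assert dbi(grid_root_length(s, GridSpec(cell=10))) == pytest.approx(0.5)


def test_dbi_tie_cells_count_horizontal():
    # diagonal cell centres (5, 5): |x| == |y| goes to the inter-row sum
    g = grid_root_length(seg([(2, 2, -10), (8, 8, -10)]), GridSpec(cell=10))
    assert dbi(g) == pytest.approx(1.0)


def test_row_biased_cross_fixture_dbi():
    g = grid_root_length(make_fixture("row_biased_cross").segments(), GridSpec(cell=10))
    assert dbi(g) == pytest.approx(-0.5)


# ---------------------------------------------------------------------------
# outside fraction

def test_all_inside_box():
    assert outside_fraction(seg([(0, 0, -10), (50, 20, -50)])) == 0.0


def test_half_outside_along_row():
    f = outside_fraction(make_fixture("L_shape_boundary").segments())
    assert f == pytest.approx(0.5)


def test_outside_matches_subdivision_oracle(rng):
    s = random_segments(rng, n_roots=6, n_points=7, scale=150)
    f = outside_fraction(s, DEFAULT_BOX)
    oracle = partition_oracle(s, box_label(DEFAULT_BOX))
    total = s.lengths.sum()
    expected = oracle.get(OUTSIDE, 0.0) / total
    assert abs(f - expected) < 1e-6


def test_zero_length_undefined():
    s = SegmentList(np.zeros((1, 3)), np.zeros((1, 3)))
    with pytest.warns(UserWarning):
        assert np.isnan(outside_fraction(s))


# ---------------------------------------------------------------------------
# aggregator

def test_aggregator_single_vertical_root_with_weight():
    arch = make_fixture("straight_vertical_100")
    arch.weights.root = 2.0
    t = compute_rsa_traits(arch)
    assert t.total_root_length == pytest.approx(100.0)
    assert t.srl == pytest.approx(50.0)
    assert t.max_rooting_depth == pytest.approx(120.0)  # stem base 20 below surface


def test_aggregator_without_weights_has_no_srl():
    t = compute_rsa_traits(make_fixture("straight_vertical_100"))
    assert t.srl is None
    assert t.total_root_length == pytest.approx(100.0)


def test_aggregator_equals_manual_composition(rng):
    from vinearch.synthetic import ARCHETYPES, generate_plant

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        arch = generate_plant(ARCHETYPES["intermediate"], "T4", seed=11)
        t = compute_rsa_traits(arch)
        segs = arch.segments()
        assert t.total_root_length == total_root_length(segs)
        assert t.max_rooting_depth == max_rooting_depth(segs, arch.soil_surface_z)
        assert t.max_horizontal_spread == max_horizontal_spread(segs)
        assert t.dbi == dbi(grid_root_length(segs, GridSpec()))
        assert t.outside_fraction == outside_fraction(segs, DEFAULT_BOX)
        np.testing.assert_array_equal(
            t.layers.lengths,
            root_length_by_layer(segs, t.layers.profile, arch.soil_surface_z).lengths)
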