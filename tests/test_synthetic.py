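import warnings
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from vinearch.core import STEM_BASE_Z
from vinearch.io_rsml import write_rsml
from vinearch.rsa_traits import (
    GridSpec,
    aspect_ratio,
    convex_hulls,
    dbi,
    grid_root_length,
    max_rooting_depth,
    outside_fraction,
    total_root_length,
)
from vinearch.shoot_leaf import internode_lengths, shoot_lengths
from vinearch.synthetic import (
    ARCHETYPES,
    CohortSpec,
    GenotypeArchetype,
    generate_cohort,
    generate_plant,
    generate_root_system,
    generate_shoot,
    make_fixture,
)


def flat_segments(roots):
    from vinearch.core import flatten_segments

    return flatten_segments(roots)


# ---------------------------------------------------------------------------
# fixtures

def test_fixture_straight_vertical():
    f = make_fixture("straight_vertical_100")
    segs = f.segments()
    assert total_root_length(segs) == pytest.approx(100.0)
    assert max_rooting_depth(segs, f.soil_surface_z) == pytest.approx(120.0)
    assert convex_hulls(segs).degenerate3d


def test_fixture_cube():
    segs = make_fixture("cube_cloud_10cm").segments()
    assert convex_hulls(segs).volume3d == pytest.approx(1.0)


def test_fixture_boundary():
    segs = make_fixture("L_shape_boundary").segments()
    assert outside_fraction(segs) == pytest.approx(0.5)


def test_fixture_cross_dbi():
    segs = make_fixture("row_biased_cross").segments()
    assert dbi(grid_root_length(segs, GridSpec(cell=10))) == pytest.approx(-0.5)


def test_unknown_fixture_lists_catalogue():
    with pytest.raises(KeyError, match="straight_vertical_100"):
        make_fixture("nope")


# ---------------------------------------------------------------------------
# root generator

def test_limit_case_pure_gravitropism():
    a = GenotypeArchetype(name="plumb", gravitropism=1.0, row_bias=0.0,
                          n_adventitious=1.0, elongation_rate=10.0,
                          branch_density=0.0, direction_noise=0.0,
                          schedule={"T4": 10})
    rs = generate_root_system(a, "T4", seed=0)
    # initial tilt washes out as gravitropism accumulates; the system must
    # be a single unbranched axis ending well below 10 steps x 10 cm x ~1
    assert len(rs) >= 1
    assert all(r.parent_id is None for r in rs)
    segs = flat_segments(rs)
    depth = max_rooting_depth(segs, -5.0)
    assert depth > 90.0  # ~100 cm of growth + 20 cm stem-base offset
    # final heading is essentially vertical
    tip = rs.roots[0].polyline
    d = tip[-1] - tip[-2]
    assert abs(d[2]) / np.linalg.norm(d) > 0.99


def test_roots_start_at_stem_base():
    rs = generate_root_system(ARCHETYPES["deep"], "T1", seed=3)
    for r in rs:
        if r.parent_id is None:
            np.testing.assert_allclose(r.polyline[0], [0, 0, STEM_BASE_Z])


def test_identical_seed_identical_rsml_bytes(tmp_path):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p1 = generate_plant(ARCHETYPES["intermediate"], "T3", seed=77, plant_id="x")
        p2 = generate_plant(ARCHETYPES["intermediate"], "T3", seed=77, plant_id="x")
    f1 = write_rsml(p1, tmp_path / "a.rsml")
    f2 = write_rsml(p2, tmp_path / "b.rsml")
    assert f1.read_bytes() == f2.read_bytes()


def test_depth_increases_with_gravitropism():
    """Spearman correlation between g and mean max depth, other params fixed."""
    gs = np.linspace(0.1, 0.95, 8)
    depths = []
    base = replace(ARCHETYPES["intermediate"], branch_density=0.0, row_bias=0.4)
    for g in gs:
        a = replace(base, gravitropism=float(g))
        vals = [max_rooting_depth(flat_segments(generate_root_system(a, "T4", seed=s)), -5.0)
                for s in range(7)]
        depths.append(np.mean(vals))
    rho = stats.spearmanr(gs, depths).statistic
    assert rho > 0.9


def test_row_bias_flattens_aspect_ratio():
    """Stronger row bias -> more along-row elongation -> lower aspect ratio."""
    base = replace(ARCHETYPES["intermediate"], branch_density=0.0,
                   gravitropism=0.3, row_bias_decay=1.0)
    ars = []
    for beta in (0.0, 1.5):
        vals = []
        for s in range(8):
            segs = flat_segments(generate_root_system(replace(base, row_bias=beta),
                                                      "T4", seed=s))
            vals.append(aspect_ratio(convex_hulls(segs)))
        ars.append(np.mean(vals))
    assert ars[1] < ars[0]


def test_dormancy_plateau_between_t2_t3():
    """The T2 -> T3 step difference is small next to in-season steps."""
    sched = ARCHETYPES["deep"].schedule
    assert sched["T3"] - sched["T2"] < sched["T2"] - sched["T1"]
    assert sched["T3"] - sched["T2"] < sched["T4"] - sched["T3"]
    lengths = {}
    for tp in ("T2", "T3", "T4"):
        vals = [total_root_length(flat_segments(
            generate_root_system(ARCHETYPES["deep"], tp, seed=s))) for s in range(6)]
        lengths[tp] = np.mean(vals)
    assert lengths["T3"] - lengths["T2"] < lengths["T4"] - lengths["T3"]


def test_branching_orders_bounded():
    rs = generate_root_system(ARCHETYPES["shallow_wide"], "T4", seed=1)
    assert max(r.order for r in rs) <= ARCHETYPES["shallow_wide"].max_order
    assert any(r.order > 0 for r in rs)


# ---------------------------------------------------------------------------
# shoot generator

def test_lateral_probability_zero_gives_main_only():
    a = replace(ARCHETYPES["deep"], lateral_probability=0.0)
    shoots = generate_shoot(a, "T3", seed=4)
    assert shoots.laterals == []


def test_internode_sd_zero_gives_equal_internodes():
    a = replace(ARCHETYPES["deep"], internode_sd=0.0, lateral_probability=0.0)
    shoots = generate_shoot(a, "T3", seed=4)
    il = internode_lengths(shoots.main)
    np.testing.assert_allclose(il, a.internode_mean, rtol=1e-12)


def test_internode_marginal_matches_configuration():
    """Sample mean internode length within 3 SE of the lognormal mean."""
    a = replace(ARCHETYPES["intermediate"], lateral_probability=0.0)
    samples = np.concatenate([
        internode_lengths(generate_shoot(a, "T4", seed=s).main) for s in range(30)])
    expected = a.internode_mean * np.exp(a.internode_sd ** 2 / 2)
    se = samples.std(ddof=1) / np.sqrt(len(samples))
    assert abs(samples.mean() - expected) < 3 * se


def test_shoot_totals_recompose():
    shoots = generate_shoot(ARCHETYPES["shallow_wide"], "T3", seed=6)
    sl = shoot_lengths(shoots)
    assert sl["total"] == pytest.approx(sl["main"] + sl["secondary"])


# ---------------------------------------------------------------------------
# cohorts

def test_cohort_file_layout(tmp_path):
    spec = CohortSpec(archetypes={"deep": 3, "shallow_wide": 3, "intermediate": 3},
                      master_seed=5, time_point="T2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        plants = generate_cohort(spec, out_dir=tmp_path)
    assert len(plants) == 9
    assert len(list(tmp_path.glob("*.rsml"))) == 9
    assert (tmp_path / "weights.csv").exists()
    assert (tmp_path / "manifest.json").exists()


def test_cohort_extensible_without_perturbing_existing():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        small = generate_cohort(CohortSpec(archetypes={"deep": 2}, master_seed=9))
        big = generate_cohort(CohortSpec(archetypes={"deep": 4}, master_seed=9))
    for a, b in zip(small, big[:2]):
        np.testing.assert_array_equal(a.roots.roots[0].polyline,
                                      b.roots.roots[0].polyline)
        assert a.weights.root == b.weights.root


def test_deep_vs_shallow_root_shoot_ratio_contrast():
    """Built-in allocation contrast: deep archetype invests more below ground."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        plants = generate_cohort(CohortSpec(
            archetypes={"deep": 8, "shallow_wide": 8}, master_seed=21))
    ratios = {"deep": [], "shallow_wide": []}
    for p in plants:
        ratios[p.genotype].append(p.weights.root / p.weights.shoot)
    stat = stats.mannwhitneyu(ratios["deep"], ratios["shallow_wide"],
                              alternative="greater")
    assert stat.pvalue < 0.01
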