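"""Synthetic whole-plant architectures for pipeline testing.

A stochastic apical-growth model generates root systems with the
qualitative structure of excavated field-grown grafted vines: adventitious
axes start at the buried stem base (z = −25 cm), grow by fixed-length
steps whose direction is pulled toward vertical by a gravitropism
parameter ``g`` and toward the planting row (±y) by a row-bias parameter
``beta``, and branch into shorter higher-order laterals behind the apex.
Shoots are phytomer chains with lognormal internodes, optional lateral
shoots and six-landmark leaves. Compartment dry weights follow from organ
lengths via per-tissue linear densities with lognormal noise.

Three genotype archetypes contrast a deep, vertically oriented habit, a
shallow wide-spreading habit, and an intermediate one — the qualitative
phenotype contrast reported for 110R-type vs. 101-14-type vs. SO4-type
rootstocks. The archetype defaults are chosen to reproduce the *ordering*
of the field phenotypes (depth, spread, root:shoot ratio), not their exact
magnitudes. Everything is reproducible from a single master seed; each
plant consumes an independent child stream, so enlarging a cohort never
perturbs existing plants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .core import (
    STEM_BASE_Z,
    CompartmentWeights,
    LeafLandmarks,
    Phytomer,
    PlantArchitecture,
    Root,
    RootSystem,
    ShootAxis,
    ShootSystem,
)
from .io_rsml import write_rsml

__all__ = ["GenotypeArchetype", "CohortSpec", "ARCHETYPES",
           "generate_root_system", "generate_shoot", "generate_plant",
           "generate_cohort", "make_fixture", "FIXTURE_CATALOGUE"]

#: Cumulative root growth steps available at each excavation time point.
#: T1/T2 fall in the first season, T3/T4 in the second; the T2 -> T3 gap is
#: small because winter dormancy contributes no elongation steps.
DEFAULT_SCHEDULE = {"T1": 5, "T2": 10, "T3": 12, "T4": 18}
#: Shoot growth steps (phytomers appear only in the growing season).
SHOOT_SCHEDULE = {"T1": 4, "T2": 12, "T3": 22, "T4": 40}
#: Time points digitized after leaf fall carry no leaves.
LEAFLESS = {"T2", "T4"}
#: Secondary-thickening multiplier on tissue linear densities per age:
#: young organs are thin (high specific root/shoot length), older ones
#: accumulate radial growth, so weight per cm rises several-fold over the
#: first two seasons.
AGE_THICKENING = {"T1": 0.16, "T2": 0.40, "T3": 0.70, "T4": 1.0}


@dataclass(frozen=True)
class GenotypeArchetype:
    """Growth-model parameter bundle for one rootstock habit.

    Parameters
    ----------
    gravitropism : float in [0, 1]
        Pull toward vertical per growth step; 1 gives straight plumb roots.
    row_bias : float >= 0
        Anisotropic pull toward the +-y (planting row) directions. The
        pull decays geometrically with step count (``row_bias_decay``):
        young root tips follow the loosened planting-row soil, older tips
        wander or dive, which keeps the system within a realistic
        along-row extent.
    n_adventitious : float
        Mean number of adventitious axes (Poisson, floor 1).
    elongation_rate : float
        cm of apical extension per growth step per root tip.
    branch_density : float
        Lateral initiations per cm of parent axis.
    branch_delay : float
        Unbranched apical zone length (cm).
    max_order : int
        Deepest branching order generated (0 = adventitious).
    tissue_density : tuple
        g dry weight per cm of root axis, by branching order.
    """

    name: str
    gravitropism: float = 0.6
    row_bias: float = 0.9
    row_bias_decay: float = 0.75
    n_adventitious: float = 7.0
    elongation_rate: float = 8.0
    branch_density: float = 0.05
    branch_delay: float = 10.0
    max_order: int = 2
    direction_noise: float = 0.5
    tissue_density: tuple = (0.060, 0.022, 0.010)
    # shoot side
    phytomer_rate: float = 1.0          # phytomers per shoot step
    internode_mean: float = 10.0        # cm, lognormal location (median)
    internode_sd: float = 0.25          # lognormal sigma on log scale
    lateral_probability: float = 0.40   # lateral shoot per main node
    lateral_phytomers: int = 6
    vein_length_mean: float = 6.0       # cm, secondary leaf veins
    vein_length_sd: float = 1.0
    shoot_density: float = 0.13         # g per cm of shoot axis
    stem_density: float = 3.0           # g per cm of buried stem
    leaf_mass_per_area: float = 0.0075  # g per cm^2
    schedule: dict = field(default_factory=lambda: dict(DEFAULT_SCHEDULE))

    def __post_init__(self) -> None:
        if not 0 <= self.gravitropism <= 1:
            raise ValueError("gravitropism must be in [0, 1]")
        if self.row_bias < 0 or self.elongation_rate < 0 or self.branch_density < 0:
            raise ValueError("rates must be >= 0")
        if not 0 <= self.lateral_probability <= 1:
            raise ValueError("lateral_probability must be in [0, 1]")


#: Default archetypes: deep/vertical, shallow/wide, and intermediate habit.
#: Parameter values were fixed once to land each archetype in the realistic
#: range for an 18-month field vine (total root length around 4-6 m x 10,
#: rooting depth 1.2-1.8 m, spread 1.2-1.5 m, under ~12 % of root length
#: beyond the planting area, root:shoot dry-weight ratio ~0.8-2) while
#: preserving the habit orderings the analysis is meant to detect.
ARCHETYPES = {
    "deep": GenotypeArchetype(
        name="deep", gravitropism=0.95, row_bias=0.8, n_adventitious=7.0,
        elongation_rate=8.3, branch_density=0.060, direction_noise=0.45,
        tissue_density=(0.078, 0.027, 0.012),
        internode_mean=9.0, lateral_probability=0.25, vein_length_mean=5.0,
        shoot_density=0.14, stem_density=4.0),
    "shallow_wide": GenotypeArchetype(
        name="shallow_wide", gravitropism=0.50, row_bias=1.1, n_adventitious=10.0,
        elongation_rate=6.5, branch_density=0.070, direction_noise=0.65,
        tissue_density=(0.050, 0.018, 0.008),
        internode_mean=10.0, lateral_probability=0.45, vein_length_mean=7.0,
        shoot_density=0.155, stem_density=2.6),
    "intermediate": GenotypeArchetype(
        name="intermediate", gravitropism=0.68, row_bias=0.9, n_adventitious=8.0,
        elongation_rate=7.4, branch_density=0.055, direction_noise=0.55,
        tissue_density=(0.055, 0.020, 0.009),
        internode_mean=10.0, lateral_probability=0.45, vein_length_mean=6.0,
        shoot_density=0.13, stem_density=2.8),
}


@dataclass(frozen=True)
class CohortSpec:
    """A cohort to generate: ``{archetype_name: n_plants}`` at one time point."""

    archetypes: dict
    master_seed: int = 0
    time_point: str = "T4"

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.archetypes.values()):
            raise ValueError("every archetype needs n >= 1 plants")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([0.0, 0.0, -1.0])


def _grow_axis(start: np.ndarray, direction: np.ndarray, n_steps: int,
               a: GenotypeArchetype, y_sign: float,
               rng: np.random.Generator) -> np.ndarray:
    """Apical growth: each step blends the previous heading with the
    gravitropic pull (−z), the row bias (±y) and isotropic noise."""
    pts = [start]
    d = _unit(direction)
    for k in range(n_steps):
        pull = (a.gravitropism * np.array([0.0, 0.0, -1.0])
                + a.row_bias * (a.row_bias_decay ** k) * np.array([0.0, y_sign, 0.0]))
        d = _unit(d + pull + rng.normal(0.0, a.direction_noise, 3))
        step = a.elongation_rate * (1.0 + rng.normal(0.0, 0.12))
        pts.append(pts[-1] + max(step, 0.5) * d)
    return np.vstack(pts)


def _point_at(poly: np.ndarray, s: float) -> tuple[np.ndarray, np.ndarray]:
    """Point and local direction at arc length ``s`` along a polyline."""
    seg = np.diff(poly, axis=0)
    lens = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(lens)])
    s = min(max(s, 0.0), cum[-1])
    i = int(np.searchsorted(cum[1:], s, side="right"))
    i = min(i, len(lens) - 1)
    frac = 0.0 if lens[i] == 0 else (s - cum[i]) / lens[i]
    return poly[i] + frac * seg[i], _unit(seg[i])


def generate_root_system(a: GenotypeArchetype, time_point: str = "T4",
                         seed: Union[int, np.random.Generator] = 0) -> RootSystem:
    """Generate one stochastic root system for an archetype and time point.

    Adventitious axes start at the buried stem base (0, 0, −25) with
    downward-tilted initial directions; each prefers one of the two
    along-row directions. Laterals initiate at ``branch_density`` per cm
    behind a ``branch_delay`` apical zone, recursively up to ``max_order``,
    with shorter growth allowances per order. Fully deterministic for a
    given seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    steps = a.schedule[time_point] if time_point in a.schedule else int(time_point)
    n_adv = max(1, int(rng.poisson(a.n_adventitious)))
    base = np.array([0.0, 0.0, STEM_BASE_Z])
    roots: list[Root] = []
    counter = [0]

    def spawn(start, direction, n_steps, order, parent_id, y_sign):
        counter[0] += 1
        rid = f"r{counter[0]}" if parent_id is None else f"{parent_id}.{counter[0]}"
        sub = replace(a, elongation_rate=a.elongation_rate * (0.55 ** order))
        poly = _grow_axis(start, direction, n_steps, sub, y_sign, rng)
        roots.append(Root(id=rid, polyline=poly, parent_id=parent_id, order=order))
        if order >= a.max_order:
            return
        length = float(np.linalg.norm(np.diff(poly, axis=0), axis=1).sum())
        branchable = max(length - a.branch_delay, 0.0)
        n_lat = rng.poisson(a.branch_density * branchable)
        for _ in range(n_lat):
            s = rng.uniform(0.0, branchable)
            p, dloc = _point_at(poly, s)
            # laterals leave roughly perpendicular to the parent axis
            perp = _unit(np.cross(dloc, rng.normal(size=3)))
            child_steps = max(2, n_steps // 2)
            spawn(p, _unit(0.7 * perp + 0.3 * dloc), child_steps,
                  order + 1, rid, y_sign)

    for _ in range(n_adv):
        y_sign = -1.0 if rng.random() < 0.5 else 1.0
        tilt = rng.uniform(0.25, 1.0)  # downward component
        horiz = rng.normal(size=2)
        d0 = _unit(np.array([horiz[0], horiz[1] + a.row_bias * y_sign, -2.0 * tilt]))
        spawn(base.copy(), d0, steps, 0, None, y_sign)
    return RootSystem(roots)


def generate_shoot(a: GenotypeArchetype, time_point: str = "T4",
                   seed: Union[int, np.random.Generator] = 0) -> ShootSystem:
    """Generate a phytomer-chain shoot with laterals and six-point leaves.

    Internode lengths are lognormal with configured median/sigma; nodes
    stack mostly upward with small horizontal jitter. Leaves are drawn only
    for time points in the growing season (after-leaf-fall time points in
    ``LEAFLESS`` produce a defoliated shoot).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_phyt = max(1, int(round(SHOOT_SCHEDULE.get(time_point, 30) * a.phytomer_rate)))
    leafy = time_point not in LEAFLESS

    def make_leaf(node: np.ndarray) -> LeafLandmarks:
        vl = max(rng.normal(a.vein_length_mean, a.vein_length_sd), 1.0)
        vr = max(rng.normal(a.vein_length_mean, a.vein_length_sd), 1.0)
        midrib = 0.9 * (vl + vr)  # comfortably above the 3-cm digitization floor
        az = rng.uniform(0, 2 * np.pi)
        u = np.array([np.cos(az), np.sin(az), 0.0])
        w = np.array([-np.sin(az), np.cos(az), 0.0])
        pl1 = node + rng.normal(0, 0.3, 3)
        pl2 = pl1 + 2.0 * u
        pl3 = pl2 + 0.35 * midrib * u
        pl4 = pl2 + midrib * u
        pl5 = pl3 + vl * _unit(0.55 * u + 0.83 * w)
        pl6 = pl3 + vr * _unit(0.55 * u - 0.83 * w)
        return LeafLandmarks(np.vstack([pl1, pl2, pl3, pl4, pl5, pl6]))

    def chain(start: np.ndarray, n: int, scale: float) -> list[np.ndarray]:
        pts = [start]
        for _ in range(n):
            ln = scale * rng.lognormal(np.log(a.internode_mean), a.internode_sd)
            d = _unit(np.array([rng.normal(0, 0.25), rng.normal(0, 0.25), 1.0]))
            pts.append(pts[-1] + ln * d)
        return pts

    base = np.array([0.0, 0.0, 0.0])          # grafting point
    init = base + np.array([0.0, 0.0, 2.0])   # shoot initiation point
    nodes = chain(init, n_phyt, 1.0)[1:]
    phytomers = [Phytomer(node=p, rank=i + 1) for i, p in enumerate(nodes)]
    for ph in phytomers:
        if leafy:
            ph.leaf = make_leaf(ph.node)
        if rng.random() < a.lateral_probability and ph.rank > 2:
            lat_nodes = chain(ph.node, max(2, a.lateral_phytomers), 0.6)[1:]
            lat = ShootAxis([Phytomer(node=p, rank=i + 1,
                                      leaf=make_leaf(p) if leafy else None)
                             for i, p in enumerate(lat_nodes)])
            ph.lateral = lat
    return ShootSystem(main=ShootAxis(phytomers, is_main=True),
                       base_path=np.vstack([base, init, nodes[0]]))


def _root_weight(roots: RootSystem, a: GenotypeArchetype, thick: float,
                 rng: np.random.Generator) -> float:
    dens = a.tissue_density
    w = sum(dens[min(r.order, len(dens) - 1)] * r.length for r in roots)
    return float(w * thick * rng.lognormal(0.0, 0.10))


def generate_plant(a: GenotypeArchetype, time_point: str = "T4",
                   seed: Union[int, np.random.Generator] = 0,
                   plant_id: str = "plant") -> PlantArchitecture:
    """Generate one complete vine: roots, shoot, stem and dry weights."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    roots = generate_root_system(a, time_point, rng)
    shoots = generate_shoot(a, time_point, rng)
    from .shoot_leaf import shoot_lengths, total_leaf_area  # local: avoid cycle
    sl = shoot_lengths(shoots)
    stem = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, STEM_BASE_Z]])
    leaf_area_cm2 = total_leaf_area(shoots)
    thick = AGE_THICKENING.get(time_point, 1.0)
    weights = CompartmentWeights(
        root=_root_weight(roots, a, thick, rng),
        stem=float(a.stem_density * thick * abs(STEM_BASE_Z) * rng.lognormal(0.0, 0.08)),
        shoot=float(a.shoot_density * thick * sl["total"] * rng.lognormal(0.0, 0.10)),
        leaf=(float(a.leaf_mass_per_area * leaf_area_cm2 * rng.lognormal(0.0, 0.10))
              if time_point not in LEAFLESS else 0.0),
    )
    return PlantArchitecture(plant_id=plant_id, roots=roots, shoots=shoots,
                             genotype=a.name, time_point=time_point,
                             weights=weights, stem=stem)


def generate_cohort(spec: CohortSpec,
                    out_dir: Optional[Union[str, Path]] = None
                    ) -> list[PlantArchitecture]:
    """Generate a cohort of plants; optionally write the file layout the
    command-line pipeline consumes (one RSML per plant, ``weights.csv``,
    ``manifest.json``).

    Each plant draws from a child stream of ``(master_seed, plant_index)``,
    so adding archetypes or plants never changes already-generated ones.
    """
    plants: list[PlantArchitecture] = []
    idx = 0
    for name, n in spec.archetypes.items():
        a = ARCHETYPES[name] if isinstance(name, str) else name
        for k in range(n):
            child = np.random.SeedSequence([spec.master_seed, idx])
            rng = np.random.default_rng(child)
            pid = f"{a.name}_{spec.time_point}_{k + 1:02d}"
            plants.append(generate_plant(a, spec.time_point, rng, plant_id=pid))
            idx += 1
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for p in plants:
            write_rsml(p, out / f"{p.plant_id}.rsml")
            rows.append({"plant_id": p.plant_id, "genotype": p.genotype,
                         "time_point": p.time_point,
                         "root_dry_weight": p.weights.root,
                         "stem_dry_weight": p.weights.stem,
                         "shoot_dry_weight": p.weights.shoot,
                         "leaf_dry_weight": p.weights.leaf})
        import pandas as pd
        pd.DataFrame(rows).to_csv(out / "weights.csv", index=False)
        manifest = {"master_seed": spec.master_seed, "time_point": spec.time_point,
                    "archetypes": {(a if isinstance(a, str) else a.name): n
                                   for a, n in spec.archetypes.items()},
                    "n_plants": len(plants)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return plants


# ---------------------------------------------------------------------------
# Analytic fixtures with closed-form traits

FIXTURE_CATALOGUE = ("straight_vertical_100", "cube_cloud_10cm",
                     "L_shape_boundary", "row_biased_cross")


def make_fixture(name: str) -> PlantArchitecture:
    """Return an analytic fixture whose traits are known in closed form.

    * ``straight_vertical_100`` — one plumb 100-cm root from the stem base:
      total length 100 cm, max depth 120 cm (surface at −5), degenerate hull.
    * ``cube_cloud_10cm`` — four vertical edges of a 10-cm cube: 3-D hull
      volume exactly 1 dm^3, XY hull area 1 dm^2.
    * ``L_shape_boundary`` — one 100-cm root along +y from the stem: half
      its length lies beyond the y = 50 planting-area boundary.
    * ``row_biased_cross`` — 120 cm along the row vs. 40 cm inter-row, in
      cells free of |x| = |y| ties: DBI = (40 − 120)/160 = −0.5.
    """
    z = -30.0
    if name == "straight_vertical_100":
        roots = [Root("r1", np.array([[0, 0, STEM_BASE_Z],
                                      [0, 0, STEM_BASE_Z - 100.0]]))]
    elif name == "cube_cloud_10cm":
        roots = [Root(f"r{i+1}", np.array([[x, y, -25.0], [x, y, -35.0]]))
                 for i, (x, y) in enumerate([(0, 0), (10, 0), (0, 10), (10, 10)])]
    elif name == "L_shape_boundary":
        roots = [Root("r1", np.array([[0.0, 0.0, z], [0.0, 100.0, z]]))]
    elif name == "row_biased_cross":
        roots = [Root("r1", np.array([[0.0, 10.0, z], [0.0, 130.0, z]])),   # 120 cm row
                 Root("r2", np.array([[10.0, 0.0, z], [50.0, 0.0, z]]))]    # 40 cm inter-row
    else:
        raise KeyError(f"unknown fixture {name!r}; catalogue: {FIXTURE_CATALOGUE}")
    return PlantArchitecture(plant_id=name, roots=RootSystem(roots))
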