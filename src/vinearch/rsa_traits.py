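"""Root-system architecture statistics from flattened segment geometry.

All operations consume a :class:`~vinearch.core.SegmentList` (cm units,
z positive up). Depth-based measures take the soil surface plane
explicitly: depth = ``soil_surface_z - z``, so a point at z = −35 under a
surface at z = −5 lies 30 cm deep.

Length-partitioning operations (soil layers, XY grid cells, planting-area
box) allocate each straight segment by exact clipping of its linear
parametrization — the length assigned to a region is the segment's full
3-D Euclidean length times the fraction of the parameter interval whose
projection falls inside the region. This is the unique allocation that
conserves total length and agrees with the limit of infinitely fine
subdivision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .core import SOIL_SURFACE_Z, PlantArchitecture, SegmentList, ValidationError

__all__ = [
    "SoilLayerProfile", "GridSpec", "GridDensity", "HullSummary", "LayerLengths",
    "RSATraits", "total_root_length", "max_rooting_depth", "max_horizontal_spread",
    "convex_hulls", "aspect_ratio", "root_length_by_layer", "grid_root_length",
    "dbi", "outside_fraction", "compute_rsa_traits",
    "DEFAULT_LAYER_BOUNDARIES", "DEFAULT_BOX",
]

#: Soil-horizon boundaries used for the published layer tables (cm below surface).
DEFAULT_LAYER_BOUNDARIES = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0, 210.0)
#: Planting-area boundary on the XY plane (cm): the 2 m x 1 m space per vine.
DEFAULT_BOX = ((-100.0, 100.0), (-50.0, 50.0))


@dataclass(frozen=True)
class SoilLayerProfile:
    """Increasing depth boundaries (cm below the soil surface), first = 0."""

    boundaries: tuple = DEFAULT_LAYER_BOUNDARIES

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if len(b) < 2 or b[0] != 0 or np.any(np.diff(b) <= 0):
            raise ValidationError(
                f"layer boundaries must start at 0 and strictly increase: {self.boundaries}")

    @classmethod
    def uniform(cls, thickness: float, max_depth: float) -> "SoilLayerProfile":
        """Equal-thickness bins from 0 down to ``max_depth`` (e.g. 5-cm bins)."""
        n = int(np.ceil(max_depth / thickness))
        return cls(tuple(thickness * i for i in range(n + 1)))

    @property
    def n_layers(self) -> int:
        return len(self.boundaries) - 1

    def labels(self) -> list[str]:
        b = self.boundaries
        return [f"{b[i]:g}-{b[i + 1]:g}" for i in range(self.n_layers)]


@dataclass(frozen=True)
class GridSpec:
    """XY grid centred on the stem: cell (i, j) covers
    [i*cell, (i+1)*cell) x [j*cell, (j+1)*cell) cm."""

    cell: float = 10.0
    origin: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValidationError(f"grid cell size must be > 0, got {self.cell}")

    def cell_center(self, i: int, j: int) -> tuple[float, float]:
        return (self.origin[0] + (i + 0.5) * self.cell,
                self.origin[1] + (j + 0.5) * self.cell)


@dataclass
class GridDensity:
    """Root length per XY grid cell, with the normalized fraction map."""

    grid: GridSpec
    cell_lengths: dict  # {(i, j): cm}

    @property
    def total(self) -> float:
        return float(sum(self.cell_lengths.values()))

    @property
    def normalized(self) -> dict:
        tot = self.total
        if tot <= 0:
            return {k: 0.0 for k in self.cell_lengths}
        return {k: v / tot for k, v in self.cell_lengths.items()}


@dataclass
class HullSummary:
    """Convex-hull geometry of the root point cloud.

    ``volume3d`` in dm^3 (= cm^3 / 1000), ``area_xy`` in dm^2 (= cm^2 / 100);
    projected axis extents in cm. Degenerate clouds (fewer than 4
    non-coplanar points in 3-D, fewer than 3 non-collinear in 2-D) report 0
    with the corresponding flag set instead of raising, so sparse young
    plants do not break batch runs.
    """

    volume3d: float = 0.0
    area_xy: float = 0.0
    projx_min: float = np.nan
    projx_max: float = np.nan
    projy_min: float = np.nan
    projy_max: float = np.nan
    degenerate3d: bool = False
    degenerate2d: bool = False


@dataclass
class LayerLengths:
    """Root length per soil layer plus out-of-profile buckets (cm).

    ``above`` collects length shallower than the surface (depth < 0);
    ``below`` collects length deeper than the last boundary. Together with
    the per-layer entries they sum to the total root length exactly.
    """

    profile: SoilLayerProfile
    lengths: np.ndarray
    above: float = 0.0
    below: float = 0.0

    def as_dict(self) -> dict:
        d = dict(zip(self.profile.labels(), self.lengths.tolist()))
        d["above_surface"] = self.above
        d[f">{self.profile.boundaries[-1]:g}"] = self.below
        return d


@dataclass
class RSATraits:
    """Per-plant bundle of all root-system architecture statistics."""

    total_root_length: float
    max_rooting_depth: float
    max_horizontal_spread: float
    hull: HullSummary
    aspect_ratio: float
    dbi: float
    outside_fraction: float
    layers: LayerLengths
    srl: Optional[float] = None
    grid: Optional[GridDensity] = None

    def as_row(self) -> dict:
        """Flatten to a scalar dict suitable for one trait-table row."""
        row = {
            "total_root_length": self.total_root_length,
            "max_rooting_depth": self.max_rooting_depth,
            "max_horizontal_spread": self.max_horizontal_spread,
            "hull_volume_dm3": self.hull.volume3d,
            "convex_area_xy_dm2": self.hull.area_xy,
            "aspect_ratio": self.aspect_ratio,
            "dbi": self.dbi,
            "outside_fraction": self.outside_fraction,
            "srl": np.nan if self.srl is None else self.srl,
        }
        for label, v in zip(self.layers.profile.labels(), self.layers.lengths):
            row[f"root_length_{label}"] = float(v)
        return row


# ---------------------------------------------------------------------------
# Scalar geometry measures

def total_root_length(segs: SegmentList) -> float:
    """Sum of Euclidean segment lengths (cm); 0 for an empty system."""
    if len(segs) == 0:
        return 0.0
    return float(segs.lengths.sum())


def max_rooting_depth(segs: SegmentList,
                      soil_surface_z: float = SOIL_SURFACE_Z) -> float:
    """Deepest segment endpoint below the soil surface (cm), clamped at 0."""
    if len(segs) == 0:
        return 0.0
    depth = soil_surface_z - segs.points[:, 2]
    d = float(depth.max())
    if d < 0:
        warnings.warn("all root points lie above the soil surface; depth = 0",
                      stacklevel=2)
        return 0.0
    return max(d, 0.0)


def max_horizontal_spread(segs: SegmentList, mode: str = "diameter") -> float:
    """Horizontal extent of the root system (cm).

    ``mode="diameter"`` (default): maximum pairwise distance between XY
    projections of segment endpoints — the diameter of the projected point
    set, computed on the 2-D hull vertices. ``mode="radial"``: twice the
    maximum radial XY distance from the stem position (0, 0).
    """
    if len(segs) == 0:
        return 0.0
    xy = np.unique(segs.points[:, :2], axis=0)
    if mode == "radial":
        return 2.0 * float(np.linalg.norm(xy, axis=1).max())
    if mode != "diameter":
        raise ValueError(f"unknown spread mode {mode!r}")
    if len(xy) == 1:
        return 0.0
    try:
        hull = ConvexHull(xy)
        pts = xy[hull.vertices]
    except QhullError:
        pts = xy  # collinear cloud: brute force on the raw points
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).max())


def convex_hulls(segs: SegmentList) -> HullSummary:
    """3-D hull volume (dm^3) and XY-projection hull area (dm^2) with extents."""
    out = HullSummary()
    if len(segs) == 0:
        out.degenerate3d = out.degenerate2d = True
        return out
    pts = np.unique(segs.points, axis=0)
    out.projx_min, out.projy_min = pts[:, :2].min(axis=0)
    out.projx_max, out.projy_max = pts[:, :2].max(axis=0)
    try:
        out.volume3d = ConvexHull(pts).volume / 1000.0  # cm^3 -> dm^3
    except QhullError:
        out.degenerate3d = True
    xy = np.unique(pts[:, :2], axis=0)
    try:
        out.area_xy = ConvexHull(xy).volume / 100.0  # cm^2 -> dm^2
    except QhullError:
        out.degenerate2d = True
    return out


def aspect_ratio(h: HullSummary) -> float:
    """Inter-row x-extent over along-row y-extent of the projected hull.

    Values < 1 indicate elongation along the planting row. Returns NaN
    (with a warning) when the y-extent is zero.
    """
    dy = h.projy_max - h.projy_min
    dx = h.projx_max - h.projx_min
    if not np.isfinite(dy) or dy <= 0:
        warnings.warn("aspect ratio undefined: zero along-row extent", stacklevel=2)
        return float("nan")
    return float(dx / dy)


# ---------------------------------------------------------------------------
# Exact-clipping length partitions

def _interval_fractions(p0: np.ndarray, p1: np.ndarray,
                        lo: float, hi: float) -> np.ndarray:
    """Fraction of each segment's parameter interval with linear value in [lo, hi).

    ``p0``/``p1`` are the scalar values at the segment ends.
    """
    delta = p1 - p0
    frac = np.empty_like(p0)
    flat = delta == 0
    frac[flat] = ((p0[flat] >= lo) & (p0[flat] < hi)).astype(float)
    nz = ~flat
    with np.errstate(divide="ignore", invalid="ignore"):
        t_lo = (lo - p0[nz]) / delta[nz]
        t_hi = (hi - p0[nz]) / delta[nz]
    t0 = np.minimum(t_lo, t_hi)
    t1 = np.maximum(t_lo, t_hi)
    frac[nz] = np.clip(t1, 0.0, 1.0) - np.clip(t0, 0.0, 1.0)
    np.clip(frac, 0.0, 1.0, out=frac)
    return frac


def root_length_by_layer(segs: SegmentList,
                         profile: SoilLayerProfile = SoilLayerProfile(),
                         soil_surface_z: float = SOIL_SURFACE_Z,
                         mode: str = "proportional") -> LayerLengths:
    """Distribute each segment's length over the soil layers it traverses.

    ``mode="proportional"`` (default) weights by the exact fraction of the
    segment's parameter interval inside each layer; ``mode="equal"`` splits
    the length equally among all layers the segment touches. Length above
    the surface goes to the ``above`` bucket, length deeper than the last
    boundary to ``below``; the partition conserves total length exactly.
    """
    k = profile.n_layers
    if len(segs) == 0:
        return LayerLengths(profile, np.zeros(k))
    d0 = soil_surface_z - segs.starts[:, 2]
    d1 = soil_surface_z - segs.ends[:, 2]
    L = segs.lengths
    b = np.asarray(profile.boundaries, dtype=float)
    big = 1e12
    edges = np.concatenate([[-big], b, [big]])  # above | layers | below
    fracs = np.empty((k + 2, len(segs)))
    for i in range(k + 2):
        fracs[i] = _interval_fractions(d0, d1, edges[i], edges[i + 1])
    if mode == "equal":
        touched = fracs > 0
        n_touched = touched.sum(axis=0)
        n_touched[n_touched == 0] = 1
        fracs = touched / n_touched
    elif mode != "proportional":
        raise ValueError(f"unknown layer mode {mode!r}")
    alloc = fracs * L
    return LayerLengths(profile, lengths=alloc[1:-1].sum(axis=1),
                        above=float(alloc[0].sum()), below=float(alloc[-1].sum()))


def grid_root_length(segs: SegmentList, grid: GridSpec = GridSpec()) -> GridDensity:
    """Allocate root length to XY grid cells by exact segment clipping.

    Each segment's full 3-D length is split across the cells its XY
    projection crosses, in proportion to the parameter interval spent in
    each cell; a vertical segment (no XY movement) contributes entirely to
    the cell containing its projected point.
    """
    cells: dict = {}
    c = grid.cell
    ox, oy = grid.origin
    for s, e, L in zip(segs.starts, segs.ends, segs.lengths):
        x0, y0 = s[0] - ox, s[1] - oy
        x1, y1 = e[0] - ox, e[1] - oy
        dx, dy = x1 - x0, y1 - y0
        if dx == 0 and dy == 0:
            key = (int(np.floor(x0 / c)), int(np.floor(y0 / c)))
            cells[key] = cells.get(key, 0.0) + float(L)
            continue
        # parameter values where the projection crosses grid lines
        ts = [0.0, 1.0]
        for p0, dp in ((x0, dx), (y0, dy)):
            if dp != 0:
                lo, hi = sorted((p0, p0 + dp))
                for m in range(int(np.floor(lo / c)) + 1, int(np.ceil(hi / c))):
                    t = (m * c - p0) / dp
                    if 0.0 < t < 1.0:
                        ts.append(t)
        ts = np.unique(ts)
        mids = 0.5 * (ts[:-1] + ts[1:])
        dts = np.diff(ts)
        mi = np.floor((x0 + mids * dx) / c).astype(int)
        mj = np.floor((y0 + mids * dy) / c).astype(int)
        for i, j, f in zip(mi, mj, dts):
            key = (int(i), int(j))
            cells[key] = cells.get(key, 0.0) + float(L * f)
    return GridDensity(grid=grid, cell_lengths=cells)


def dbi(g: GridDensity) -> float:
    """Directional Bias Index of grid-aggregated root length, in [-1, 1].

    Cells are classified by their centre offsets from the stem:
    along-row cells (|y| > |x|) accumulate L_vertical, inter-row cells
    (|x| >= |y|, ties included) accumulate L_horizontal;
    DBI = (L_h - L_v) / (L_h + L_v). Negative values mean root length is
    biased along the planting row. NaN when total length is zero.
    """
    lh = lv = 0.0
    for (i, j), length in g.cell_lengths.items():
        xc, yc = g.grid.cell_center(i, j)
        if abs(xc) >= abs(yc):
            lh += length
        else:
            lv += length
    tot = lh + lv
    if tot <= 0:
        warnings.warn("DBI undefined: zero total grid length", stacklevel=2)
        return float("nan")
    return (lh - lv) / tot


def outside_fraction(segs: SegmentList, box: tuple = DEFAULT_BOX) -> float:
    """Fraction of root length whose XY projection falls outside a box.

    ``box = ((xmin, xmax), (ymin, ymax))`` in cm; depth is ignored. The
    default box is the 2 m x 1 m planting area per vine. Computed by exact
    clipping: the inside part of each segment is the sub-interval of its
    parametrization whose projection lies inside the (convex) box.
    NaN when total length is zero.
    """
    (xmin, xmax), (ymin, ymax) = box
    if xmax <= xmin or ymax <= ymin:
        raise ValidationError(f"box extents must be positive: {box}")
    L = segs.lengths if len(segs) else np.empty(0)
    total = float(L.sum())
    if total <= 0:
        warnings.warn("outside fraction undefined: zero total length", stacklevel=2)
        return float("nan")
    x0, y0 = segs.starts[:, 0], segs.starts[:, 1]
    x1, y1 = segs.ends[:, 0], segs.ends[:, 1]
    tin0 = np.zeros(len(segs))
    tin1 = np.ones(len(segs))
    for p0, p1, lo, hi in ((x0, x1, xmin, xmax), (y0, y1, ymin, ymax)):
        d = p1 - p0
        flat = d == 0
        inside_flat = (p0 >= lo) & (p0 <= hi)
        with np.errstate(divide="ignore", invalid="ignore"):
            ta = (lo - p0) / np.where(flat, 1.0, d)
            tb = (hi - p0) / np.where(flat, 1.0, d)
        lo_t = np.where(flat, np.where(inside_flat, 0.0, 1.0), np.minimum(ta, tb))
        hi_t = np.where(flat, np.where(inside_flat, 1.0, 0.0), np.maximum(ta, tb))
        tin0 = np.maximum(tin0, lo_t)
        tin1 = np.minimum(tin1, hi_t)
    inside = float((L * np.clip(tin1 - tin0, 0.0, 1.0)).sum())
    return float(np.clip((total - inside) / total, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Aggregator

def compute_rsa_traits(arch: PlantArchitecture,
                       profile: SoilLayerProfile = SoilLayerProfile(),
                       grid: GridSpec = GridSpec(),
                       box: tuple = DEFAULT_BOX,
                       soil_surface_z: Optional[float] = None,
                       keep_grid: bool = False) -> RSATraits:
    """Compute the full RSA trait bundle for one plant.

    Degenerate geometry produces warnings and NaN / flagged fields rather
    than exceptions, so one sparse plant never aborts a batch run. Specific
    root length (cm per g) is filled in only when the root dry weight is
    present and positive.
    """
    if soil_surface_z is None:
        soil_surface_z = arch.soil_surface_z
    segs = arch.segments()
    hull = convex_hulls(segs)
    gdens = grid_root_length(segs, grid)
    tot = total_root_length(segs)
    srl = None
    w = arch.weights.root
    if w is not None and w > 0 and tot > 0:
        srl = tot / w
    return RSATraits(
        total_root_length=tot,
        max_rooting_depth=max_rooting_depth(segs, soil_surface_z),
        max_horizontal_spread=max_horizontal_spread(segs),
        hull=hull,
        aspect_ratio=aspect_ratio(hull),
        dbi=dbi(gdens) if gdens.total > 0 else float("nan"),
        outside_fraction=outside_fraction(segs, box) if tot > 0 else float("nan"),
        layers=root_length_by_layer(segs, profile, soil_surface_z),
        srl=srl,
        grid=gdens if keep_grid else None,
    )
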