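"""Core domain containers for digitized whole-plant architectures.

Coordinate convention (used throughout the package):

* ``x`` — inter-row direction, cm
* ``y`` — along the planting row, cm
* ``z`` — vertical, positive up, cm

The origin ``(0, 0, 0)`` is the grafting point of the vine. The soil
surface sits at ``z = SOIL_SURFACE_Z`` (default −5 cm: the graft union
sticks out of the ground) and the base of the buried stem at
``z = STEM_BASE_Z`` (default −25 cm: rooted cuttings are planted with the
cane roughly 20 cm below the surface). Adventitious roots emerge from the
buried stem section; the stem itself is never counted as root length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

#: Default z of the soil surface plane (cm, graft-point origin).
SOIL_SURFACE_Z: float = -5.0
#: Default z of the buried stem base where adventitious roots attach (cm).
STEM_BASE_Z: float = -25.0
#: Child-to-parent attachment tolerance (cm); exceeding it warns, never raises.
ATTACH_TOL: float = 0.5


class ValidationError(ValueError):
    """A container violates one of its structural invariants."""


class TopologyError(ValidationError):
    """Parent/child wiring is inconsistent (missing parent, cycle...)."""


class UnitError(ValueError):
    """A file declares length units this package will not silently rescale."""


def as_points(points: Iterable) -> np.ndarray:
    """Coerce an iterable of 3-D points to a float ``(n, 3)`` array."""
    arr = np.asarray(list(points) if not isinstance(points, np.ndarray) else points,
                     dtype=float)
    if arr.ndim == 1 and arr.size == 0:
        return arr.reshape(0, 3)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValidationError(f"expected (n, 3) point array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("non-finite coordinate in point array")
    return arr


def _point_to_polyline(q: np.ndarray, poly: np.ndarray) -> float:
    """Minimum Euclidean distance from point ``q`` to a polyline (cm)."""
    a, b = poly[:-1], poly[1:]
    ab = b - a
    denom = (ab ** 2).sum(axis=1)
    t = np.where(denom > 0, ((q - a) * ab).sum(axis=1) / np.where(denom > 0, denom, 1.0), 0.0)
    t = np.clip(t, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.linalg.norm(proj - q, axis=1).min())


@dataclass
class Root:
    """One root axis: an ordered 3-D polyline with topological metadata.

    Parameters
    ----------
    id : str
        Unique identifier within the root system.
    polyline : (n, 3) array
        Digitized node coordinates in cm, n >= 2.
    parent_id : str or None
        Identifier of the mother root; ``None`` for adventitious roots,
        which attach directly to the buried stem.
    order : int
        Branching order, 0 for adventitious axes.
    properties : dict
        Opaque per-root annotations (preserved on RSML round-trip).
    """

    id: str
    polyline: np.ndarray
    parent_id: Optional[str] = None
    order: int = 0
    properties: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.polyline = as_points(self.polyline)
        if len(self.polyline) < 2:
            raise ValidationError(
                f"root {self.id!r}: polyline needs >= 2 points, got {len(self.polyline)}")

    @property
    def length(self) -> float:
        """Total Euclidean polyline length in cm."""
        return float(np.linalg.norm(np.diff(self.polyline, axis=0), axis=1).sum())


@dataclass
class RootSystem:
    """Collection of :class:`Root` axes forming one vine's root system."""

    roots: list[Root] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.roots)

    def __iter__(self):
        return iter(self.roots)

    def by_id(self, root_id: str) -> Root:
        for r in self.roots:
            if r.id == root_id:
                return r
        raise KeyError(root_id)

    def validate(self, attach_tol: float = ATTACH_TOL) -> None:
        """Check id uniqueness, parent existence, acyclicity and attachment.

        A child whose first point lies farther than ``attach_tol`` from every
        point of its parent's polyline triggers a warning (digitizer noise is
        expected at the half-centimetre scale), not an error.
        """
        ids = [r.id for r in self.roots]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate root ids: {dupes}")
        index = {r.id: r for r in self.roots}
        for r in self.roots:
            if r.parent_id is None:
                continue
            if r.parent_id not in index:
                raise TopologyError(f"root {r.id!r} references missing parent {r.parent_id!r}")
            # cycle walk
            seen = {r.id}
            cur = r
            while cur.parent_id is not None:
                if cur.parent_id in seen:
                    raise TopologyError(f"cycle in parent chain at root {cur.parent_id!r}")
                seen.add(cur.parent_id)
                cur = index[cur.parent_id]
            parent = index[r.parent_id]
            d = _point_to_polyline(r.polyline[0], parent.polyline)
            if d > attach_tol:
                warnings.warn(
                    f"root {r.id!r} starts {d:.2f} cm from parent {r.parent_id!r} "
                    f"(tolerance {attach_tol} cm)", stacklevel=2)

    @property
    def total_length(self) -> float:
        return float(sum(r.length for r in self.roots))


@dataclass
class SegmentList:
    """Flattened root geometry: straight 3-D line segments.

    ``starts``/``ends`` are ``(m, 3)`` arrays in cm; ``root_ids`` maps each
    segment back to its axis. All trait computations operate on this view.
    """

    starts: np.ndarray
    ends: np.ndarray
    root_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.starts = as_points(self.starts)
        self.ends = as_points(self.ends)
        if self.starts.shape != self.ends.shape:
            raise ValidationError("starts and ends differ in shape")
        if not self.root_ids:
            self.root_ids = [""] * len(self.starts)

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def lengths(self) -> np.ndarray:
        """Per-segment Euclidean lengths (cm)."""
        return np.linalg.norm(self.ends - self.starts, axis=1)

    @property
    def points(self) -> np.ndarray:
        """All segment endpoints, stacked (2m, 3)."""
        if len(self) == 0:
            return np.empty((0, 3))
        return np.vstack([self.starts, self.ends])


def flatten_segments(roots: RootSystem) -> SegmentList:
    """Flatten a root system to one segment per consecutive polyline point pair.

    Total Euclidean length is exactly conserved; zero-length segments (duplicate
    digitized points) are retained and contribute zero length.
    """
    starts, ends, ids = [], [], []
    for r in roots:
        starts.append(r.polyline[:-1])
        ends.append(r.polyline[1:])
        ids.extend([r.id] * (len(r.polyline) - 1))
    if not starts:
        return SegmentList(np.empty((0, 3)), np.empty((0, 3)), [])
    return SegmentList(np.vstack(starts), np.vstack(ends), ids)


# ---------------------------------------------------------------------------
# Shoot-side containers

@dataclass
class LeafLandmarks:
    """Six-point digitized leaf: PL1 petiole base, PL2 adaxial leaf base,
    PL3 midrib/vein junction, PL4 midrib tip, PL5/PL6 left/right vein tips."""

    points: np.ndarray  # (6, 3), rows PL1..PL6

    def __post_init__(self) -> None:
        self.points = as_points(self.points)
        if self.points.shape != (6, 3):
            raise ValidationError(
                f"leaf needs exactly 6 landmarks PL1..PL6, got {self.points.shape[0]}")

    def landmark(self, label: str) -> np.ndarray:
        i = int(label[2:]) - 1
        if not 0 <= i < 6:
            raise KeyError(label)
        return self.points[i]

    @property
    def vein_left(self) -> float:
        """Euclidean PL3→PL5 distance (cm): left secondary vein."""
        return float(np.linalg.norm(self.points[4] - self.points[2]))

    @property
    def vein_right(self) -> float:
        """Euclidean PL3→PL6 distance (cm): right secondary vein."""
        return float(np.linalg.norm(self.points[5] - self.points[2]))

    @property
    def primary_vein(self) -> float:
        """Euclidean PL2→PL4 distance (cm): midrib length."""
        return float(np.linalg.norm(self.points[3] - self.points[1]))


@dataclass
class Phytomer:
    """Repeating shoot unit: a node with optional leaf and lateral axis."""

    node: np.ndarray
    rank: int
    leaf: Optional[LeafLandmarks] = None
    lateral: Optional["ShootAxis"] = None

    def __post_init__(self) -> None:
        self.node = np.asarray(self.node, dtype=float).reshape(3)


@dataclass
class ShootAxis:
    """Ordered chain of phytomers; ranks run consecutively from 1."""

    phytomers: list[Phytomer]
    is_main: bool = False

    def __post_init__(self) -> None:
        if not self.phytomers:
            raise ValidationError("shoot axis needs >= 1 phytomer")
        ranks = [p.rank for p in self.phytomers]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValidationError(f"phytomer ranks not consecutive from 1: {ranks}")

    @property
    def nodes(self) -> np.ndarray:
        return np.vstack([p.node for p in self.phytomers])


@dataclass
class ShootSystem:
    """Main shoot axis plus laterals attached at their mother nodes."""

    main: Optional[ShootAxis] = None
    #: path from the grafting point to the shoot initiation point (cm);
    #: prepended to the main axis when measuring main-shoot length
    base_path: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.base_path is not None:
            self.base_path = as_points(self.base_path)

    @property
    def laterals(self) -> list[ShootAxis]:
        if self.main is None:
            return []
        return [p.lateral for p in self.main.phytomers if p.lateral is not None]

    def leaves(self) -> list[LeafLandmarks]:
        out: list[LeafLandmarks] = []
        if self.main is None:
            return out
        for p in self.main.phytomers:
            if p.leaf is not None:
                out.append(p.leaf)
            if p.lateral is not None:
                out.extend(q.leaf for q in p.lateral.phytomers if q.leaf is not None)
        return out


@dataclass
class CompartmentWeights:
    """Per-vine compartment dry weights in grams (any may be missing)."""

    root: Optional[float] = None
    stem: Optional[float] = None
    shoot: Optional[float] = None
    leaf: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("root", "stem", "shoot", "leaf"):
            v = getattr(self, name)
            if v is not None and (not np.isfinite(v) or v < 0):
                raise ValidationError(f"{name} dry weight must be >= 0, got {v}")

    @property
    def woody_total(self) -> Optional[float]:
        """Root + stem + shoot dry weight (g); leaves are excluded."""
        parts = (self.root, self.stem, self.shoot)
        if any(p is None for p in parts):
            return None
        return float(sum(parts))


@dataclass
class PlantArchitecture:
    """One vine: root system, optional shoot system and metadata."""

    plant_id: str
    roots: RootSystem = field(default_factory=RootSystem)
    shoots: Optional[ShootSystem] = None
    genotype: str = ""
    time_point: str = ""
    stem_base_z: float = STEM_BASE_Z
    soil_surface_z: float = SOIL_SURFACE_Z
    weights: CompartmentWeights = field(default_factory=CompartmentWeights)
    #: digitized stem polyline from graft point to stem base (not root length)
    stem: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.stem is not None:
            self.stem = as_points(self.stem)
        if self.stem_base_z >= self.soil_surface_z:
            raise ValidationError(
                f"stem base z ({self.stem_base_z}) must lie below the soil "
                f"surface ({self.soil_surface_z})")

    def segments(self) -> SegmentList:
        return flatten_segments(self.roots)
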