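"""Shoot architecture and leaf-area statistics from digitized geometry."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import LeafLandmarks, ShootAxis, ShootSystem

__all__ = ["LeafAreaModel", "internode_lengths", "shoot_lengths", "leaf_area",
           "total_leaf_area", "canopy_indices"]


@dataclass(frozen=True)
class LeafAreaModel:
    """Allometric single-leaf area model: area = c * (L_left * L_right)**k.

    ``L_left`` and ``L_right`` are the digitized secondary vein lengths
    (straight-line PL3→PL5 and PL3→PL6 distances, cm). The default
    coefficients (c = 0.9, k = 1.0) are an uncalibrated placeholder: to
    reproduce published cultivar leaf areas, supply coefficients from a
    leaf-area calibration for that cultivar.
    """

    c: float = 0.9
    k: float = 1.0

    def __post_init__(self) -> None:
        if self.c <= 0 or self.k <= 0:
            raise ValueError(f"leaf-area coefficients must be positive: c={self.c}, k={self.k}")


def internode_lengths(axis: ShootAxis) -> np.ndarray:
    """Euclidean distances between successive phytomer nodes, in rank order.

    A single-phytomer axis yields an empty array; duplicate nodes yield
    zero-length internodes (retained).
    """
    nodes = axis.nodes
    if len(nodes) < 2:
        return np.empty(0)
    return np.linalg.norm(np.diff(nodes, axis=0), axis=1)


def _axis_length(axis: ShootAxis) -> float:
    return float(internode_lengths(axis).sum())


def shoot_lengths(shoots: ShootSystem) -> dict:
    """Main, secondary and total shoot lengths plus counts.

    Returns ``{main, secondary, total, n_secondary, n_phytomers}`` with
    lengths in cm. The main length includes the graft-to-initiation base
    path when digitized; ``total = main + secondary`` exactly.
    ``n_phytomers`` counts phytomers on the main axis and all laterals.
    """
    if shoots.main is None:
        return {"main": 0.0, "secondary": 0.0, "total": 0.0,
                "n_secondary": 0, "n_phytomers": 0}
    main = _axis_length(shoots.main)
    if shoots.base_path is not None and len(shoots.base_path) >= 2:
        main += float(np.linalg.norm(np.diff(shoots.base_path, axis=0), axis=1).sum())
    laterals = shoots.laterals
    secondary = float(sum(_axis_length(l) for l in laterals))
    n_phyt = len(shoots.main.phytomers) + sum(len(l.phytomers) for l in laterals)
    return {"main": main, "secondary": secondary, "total": main + secondary,
            "n_secondary": len(laterals), "n_phytomers": n_phyt}


def leaf_area(leaf: LeafLandmarks, model: LeafAreaModel = LeafAreaModel()) -> float:
    """Estimated single-leaf area (cm^2) from the two secondary vein lengths.

    area = c * (L_left * L_right)**k; monotone increasing in each vein
    length. A zero vein length yields 0 with a warning. Leaves with a
    primary vein under 3 cm are excluded at digitization time; a violation
    here only warns, it is not re-filtered.
    """
    ll, lr = leaf.vein_left, leaf.vein_right
    if ll <= 0 or lr <= 0:
        warnings.warn("zero secondary vein length; leaf area = 0", stacklevel=2)
        return 0.0
    if leaf.primary_vein < 3.0:
        warnings.warn(f"leaf primary vein {leaf.primary_vein:.2f} cm < 3 cm: "
                      "should have been excluded at digitization", stacklevel=2)
    return float(model.c * (ll * lr) ** model.k)


def total_leaf_area(shoots: ShootSystem,
                    model: LeafAreaModel = LeafAreaModel()) -> float:
    """Sum of estimated areas over every digitized leaf (cm^2)."""
    return float(sum(leaf_area(l, model) for l in shoots.leaves()))


def canopy_indices(shoots: ShootSystem,
                   leaf_weight: Optional[float] = None,
                   shoot_weight: Optional[float] = None,
                   model: LeafAreaModel = LeafAreaModel()) -> dict:
    """Canopy allocation indices for one vine.

    Returns ``{total_leaf_area, sla, ssl}``: SLA = total leaf area / leaf
    dry weight (cm^2 per g), SSL = total shoot length / shoot dry weight
    (cm per g). A missing or non-positive weight makes the corresponding
    ratio NaN — leafless winter plants simply have no SLA.
    """
    area = total_leaf_area(shoots, model)
    total_len = shoot_lengths(shoots)["total"]
    sla = ssl = float("nan")
    if leaf_weight is not None:
        if leaf_weight > 0:
            sla = area / leaf_weight
        else:
            warnings.warn("non-positive leaf dry weight; SLA undefined", stacklevel=2)
    if shoot_weight is not None:
        if shoot_weight > 0:
            ssl = total_len / shoot_weight
        else:
            warnings.warn("non-positive shoot dry weight; SSL undefined", stacklevel=2)
    return {"total_leaf_area": area, "sla": sla, "ssl": ssl}
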