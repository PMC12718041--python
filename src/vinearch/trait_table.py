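"""Per-plant trait-table assembly: one row per vine, all statistics.

Combines root-system architecture traits, shoot/canopy indices and
biomass-allocation indices into a flat table ready for allometric fits and
PLS-DA. A degenerate plant yields NaN in the affected columns instead of
aborting the batch.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional

import pandas as pd

from .allometry import mass_fractions, root_shoot_ratios
from .core import PlantArchitecture
from .rsa_traits import (
    DEFAULT_BOX,
    GridSpec,
    SoilLayerProfile,
    compute_rsa_traits,
)
from .shoot_leaf import LeafAreaModel, canopy_indices, shoot_lengths

__all__ = ["build_trait_table", "plant_row"]


def plant_row(arch: PlantArchitecture,
              profile: SoilLayerProfile = SoilLayerProfile(),
              grid: GridSpec = GridSpec(),
              box: tuple = DEFAULT_BOX,
              leaf_model: LeafAreaModel = LeafAreaModel()) -> dict:
    """All computed statistics for one vine as a flat scalar dict."""
    row: dict = {"plant_id": arch.plant_id, "genotype": arch.genotype,
                 "time_point": arch.time_point}
    rsa = compute_rsa_traits(arch, profile=profile, grid=grid, box=box)
    row.update(rsa.as_row())
    shoot_total = None
    if arch.shoots is not None:
        sl = shoot_lengths(arch.shoots)
        shoot_total = sl["total"]
        row.update({"total_shoot_length": sl["total"],
                    "main_shoot_length": sl["main"],
                    "secondary_shoot_length": sl["secondary"],
                    "n_secondary_shoots": sl["n_secondary"],
                    "n_phytomers": sl["n_phytomers"]})
        ci = canopy_indices(arch.shoots, leaf_weight=arch.weights.leaf,
                            shoot_weight=arch.weights.shoot, model=leaf_model)
        row.update(ci)
    w = arch.weights
    for comp in ("root", "stem", "shoot", "leaf"):
        row[f"{comp}_dry_weight"] = getattr(w, comp)
    if w.woody_total is not None and w.woody_total > 0:
        row.update(mass_fractions(w))
    row.update(root_shoot_ratios(root_weight=w.root, shoot_weight=w.shoot,
                                 root_length=rsa.total_root_length,
                                 shoot_length=shoot_total))
    return row


def build_trait_table(plants: Iterable[PlantArchitecture],
                      profile: SoilLayerProfile = SoilLayerProfile(),
                      grid: GridSpec = GridSpec(),
                      box: tuple = DEFAULT_BOX,
                      leaf_model: LeafAreaModel = LeafAreaModel()) -> pd.DataFrame:
    """One trait row per plant; failures are warnings, never batch aborts."""
    rows = []
    for p in plants:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rows.append(plant_row(p, profile, grid, box, leaf_model))
        except Exception as e:  # a single broken plant must not kill the run
            warnings.warn(f"plant {p.plant_id!r} skipped: {e}", stacklevel=2)
    return pd.DataFrame(rows)
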