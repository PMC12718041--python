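"""Biomass-partitioning indices and standardized major axis allometry.

SMA (standardized major axis, also called reduced major axis) regression
fits a symmetric line to log-transformed trait pairs when both variables
carry measurement error — the standard model for allometric scaling of
root vs. shoot size. On (log x, log y) the slope is sign(r) * s_y / s_x
and the intercept is the line through the bivariate mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import CompartmentWeights

__all__ = ["SMAResult", "mass_fractions", "root_shoot_ratios", "sma_fit",
           "sma_fit_by_group"]


@dataclass(frozen=True)
class SMAResult:
    """Fitted SMA line on log-log axes.

    ``slope`` and ``r2`` are invariant to the log base; the intercept is on
    the scale of ``log_base`` (default base 10) and shifts when either
    variable is rescaled. ``slope_ci`` is the standard 95 % SMA interval.
    """

    slope: float
    intercept: float
    r2: float
    n: int
    slope_ci: tuple
    log_base: float = 10.0

    def __post_init__(self) -> None:
        lo, hi = self.slope_ci
        if not (min(lo, hi) <= self.slope <= max(lo, hi)):
            raise ValueError("CI does not contain the fitted slope")


def mass_fractions(w: CompartmentWeights) -> dict:
    """Woody mass fractions: each compartment over root + stem + shoot.

    Leaves are excluded from the denominator (deciduous tissue). The three
    fractions sum to 1. All-zero weights return NaN fractions with a warning.
    """
    total = w.woody_total
    if total is None:
        raise ValueError("mass fractions need root, stem and shoot dry weights")
    if total <= 0:
        warnings.warn("zero woody biomass; mass fractions undefined", stacklevel=2)
        nan = float("nan")
        return {"root_frac": nan, "stem_frac": nan, "shoot_frac": nan}
    return {"root_frac": w.root / total,
            "stem_frac": w.stem / total,
            "shoot_frac": w.shoot / total}


def root_shoot_ratios(root_weight: Optional[float] = None,
                      shoot_weight: Optional[float] = None,
                      root_length: Optional[float] = None,
                      shoot_length: Optional[float] = None) -> dict:
    """Root:shoot ratios on the biomass and length scales.

    ``biomass_ratio`` = root dry weight / shoot dry weight;
    ``length_ratio`` = total root length / total shoot length.
    A missing or zero denominator yields NaN for that ratio.
    """
    out = {"biomass_ratio": float("nan"), "length_ratio": float("nan")}
    if root_weight is not None and shoot_weight is not None and shoot_weight > 0:
        out["biomass_ratio"] = root_weight / shoot_weight
    if root_length is not None and shoot_length is not None and shoot_length > 0:
        out["length_ratio"] = root_length / shoot_length
    return out


def sma_fit(x, y, log_base: float = 10.0) -> SMAResult:
    """Standardized major axis regression on log-log transformed data.

    Parameters
    ----------
    x, y : array-like of positive reals
        Raw (untransformed) trait values; n >= 3.
    log_base : float
        Base of the log transform (10 by default; use ``np.e`` for natural
        logs). Slope and R^2 do not depend on the base, the intercept does.

    Returns
    -------
    SMAResult
        slope b = sign(r) * s_y / s_x on log axes, intercept through the
        mean, r2 = r^2, and the 95 % slope CI
        b * (sqrt(B^2 + 1) +/- B) with B = sqrt((1 - r^2)/(n - 2)) * t_{0.975, n-2}.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"SMA needs n >= 3, got {n}")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("SMA on log-log data requires strictly positive values")
    lx = np.log(x) / np.log(log_base)
    ly = np.log(y) / np.log(log_base)
    sx = lx.std(ddof=1)
    sy = ly.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance on log axis; SMA slope undefined")
    r = float(np.corrcoef(lx, ly)[0, 1])
    sign = 1.0 if r >= 0 else -1.0
    slope = sign * sy / sx
    intercept = float(ly.mean() - slope * lx.mean())
    r2 = r * r
    B = np.sqrt(max(1.0 - r2, 0.0) / (n - 2)) * stats.t.ppf(0.975, n - 2)
    ci = (slope * (np.sqrt(B * B + 1.0) - B), slope * (np.sqrt(B * B + 1.0) + B))
    lo, hi = (min(ci), max(ci))
    return SMAResult(slope=float(slope), intercept=intercept, r2=float(r2),
                     n=n, slope_ci=(float(lo), float(hi)), log_base=log_base)


def sma_fit_by_group(df: pd.DataFrame, x: str, y: str, group: str,
                     log_base: float = 10.0) -> pd.DataFrame:
    """Fit one SMA line per group (e.g. per rootstock genotype).

    Rows with non-positive or missing values in either column are dropped
    per group; groups with fewer than 3 usable rows are skipped with a
    warning. Returns one row per group with slope, intercept, r2, n and CI.
    """
    rows = []
    for g, sub in df.groupby(group, sort=True):
        sub = sub[[x, y]].dropna()
        sub = sub[(sub[x] > 0) & (sub[y] > 0)]
        if len(sub) < 3:
            warnings.warn(f"group {g!r}: only {len(sub)} usable rows; skipped",
                          stacklevel=2)
            continue
        res = sma_fit(sub[x].to_numpy(), sub[y].to_numpy(), log_base)
        rows.append({group: g, "slope": res.slope, "intercept": res.intercept,
                     "r2": res.r2, "n": res.n,
                     "slope_ci_lo": res.slope_ci[0], "slope_ci_hi": res.slope_ci[1]})
    return pd.DataFrame(rows)
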