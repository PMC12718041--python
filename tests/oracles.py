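"""Independent oracles for length-partitioning and hull computations.

These deliberately avoid the package's exact-clipping code path: each
segment's parameter interval is cut into 1e4 uniform chunks, every chunk is
checked at both ends and its midpoint with a vectorized region-labelling
function, and any chunk that straddles a region change is recursively
bisected (to 1e-12 in parameter) before its length is assigned to the
region of its midpoint. Hull volumes/areas are checked by
rejection-sampling Monte Carlo.
"""

from __future__ import annotations

import numpy as np

N_CHUNKS = 10_000
_T_EPS = 1e-12


def _refine(p0, dp, length, t0, t1, l0, l1, label1, acc):
    stack = [(t0, t1, l0, l1)]
    while stack:
        a, b, la, lb = stack.pop()
        if la == lb or (b - a) < _T_EPS:
            mid = 0.5 * (a + b)
            lab = label1(p0 + mid * dp)
            acc[lab] = acc.get(lab, 0.0) + length * (b - a)
        else:
            m = 0.5 * (a + b)
            lm = label1(p0 + m * dp)
            stack.append((a, m, la, lm))
            stack.append((m, b, lm, lb))


def partition_oracle(segs, vec_label):
    """Map region code -> allocated length. ``vec_label`` takes an (m, 3)
    point array and returns an integer region code per point."""
    acc: dict = {}

    def label1(p):
        return int(vec_label(p[None, :])[0])

    ts = np.linspace(0.0, 1.0, 2 * N_CHUNKS + 1)  # ends and midpoints
    for s, e, L in zip(segs.starts, segs.ends, segs.lengths):
        if L == 0:
            continue
        dp = e - s
        labels = vec_label(s[None, :] + ts[:, None] * dp[None, :])
        l0, lm, l1 = labels[0:-1:2], labels[1::2], labels[2::2]
        ok = (l0 == lm) & (lm == l1)
        if ok.any():
            counts = np.bincount(lm[ok] - lm[ok].min(),
                                 weights=np.full(int(ok.sum()), L / N_CHUNKS))
            base = int(lm[ok].min())
            for off, w in enumerate(counts):
                if w > 0:
                    acc[base + off] = acc.get(base + off, 0.0) + float(w)
        dt = 1.0 / N_CHUNKS
        for i in np.where(~ok)[0]:
            _refine(s, dp, float(L), i * dt, (i + 1) * dt,
                    int(l0[i]), int(l1[i]), label1, acc)
    return acc


# region code helpers -------------------------------------------------------

ABOVE, BELOW = -1, -2


def layer_label(soil_surface_z, boundaries):
    """Codes: layer index 0..k-1, ABOVE for depth < 0, BELOW past the last
    boundary."""
    b = np.asarray(boundaries, dtype=float)
    k = len(b) - 1

    def fn(pts):
        d = soil_surface_z - pts[:, 2]
        idx = np.searchsorted(b, d, side="right") - 1
        out = np.where(d < 0, ABOVE, np.where(idx >= k, BELOW, idx))
        return out.astype(int)
    return fn


GRID_ENC = 10_000  # code = (i + GRID_ENC//2) * GRID_ENC + (j + GRID_ENC//2)


def grid_label(cell, origin=(0.0, 0.0)):
    def fn(pts):
        i = np.floor((pts[:, 0] - origin[0]) / cell).astype(int)
        j = np.floor((pts[:, 1] - origin[1]) / cell).astype(int)
        return (i + GRID_ENC // 2) * GRID_ENC + (j + GRID_ENC // 2)
    return fn


def grid_code(i, j):
    return (i + GRID_ENC // 2) * GRID_ENC + (j + GRID_ENC // 2)


INSIDE, OUTSIDE = 0, 1


def box_label(box):
    (xmin, xmax), (ymin, ymax) = box

    def fn(pts):
        inside = ((pts[:, 0] >= xmin) & (pts[:, 0] <= xmax)
                  & (pts[:, 1] >= ymin) & (pts[:, 1] <= ymax))
        return np.where(inside, INSIDE, OUTSIDE)
    return fn


def mc_hull_volume(points, n=1_000_000, seed=0):
    """Monte-Carlo convex-hull volume (same units as coordinates^dim)."""
    from scipy.spatial import ConvexHull
    pts = np.asarray(points, dtype=float)
    hull = ConvexHull(pts)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    rng = np.random.default_rng(seed)
    sample = rng.uniform(lo, hi, size=(n, pts.shape[1]))
    A, b = hull.equations[:, :-1], hull.equations[:, -1]
    inside = np.all(sample @ A.T + b <= 1e-12, axis=1)
    return float(np.prod(hi - lo) * inside.mean())
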