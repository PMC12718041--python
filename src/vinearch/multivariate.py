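"""PLS-DA of architectural trait tables: NIPALS fitting, Q² cross-validation
and variable-importance-in-projection (VIP) scores.

Partial least squares discriminant analysis projects a plants × traits
matrix onto a small number of latent components that maximize covariance
with class membership (here, rootstock genotype). The response is the
dummy-coded class matrix; both blocks are centered, and predictors are
scaled to unit variance. Components are extracted with the classical
non-linear iterative partial least squares (NIPALS) algorithm, implemented
here in full so every intermediate (weights, loadings, scores) is exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PLSDAModel", "standardize", "plsda_fit", "q2_cv", "vip",
           "permutation_test"]

_TOL = 1e-13
_MAX_ITER = 1000


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def standardize(X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center columns and scale to unit variance (sample sd, ddof = 1).

    Returns ``(X_scaled, means, sds)``. A missing cell or a constant column
    is an error naming the offending plant/trait — silent imputation would
    corrupt the projection.
    """
    Xm, names = _as_matrix(X)
    if np.any(~np.isfinite(Xm)):
        bad = np.argwhere(~np.isfinite(Xm))
        locs = [f"(row {i}, trait {names[j]})" for i, j in bad[:5]]
        raise ValueError(f"missing/non-finite cells: {', '.join(locs)}")
    means = Xm.mean(axis=0)
    sds = Xm.std(axis=0, ddof=1)
    const = np.where(sds == 0)[0]
    if const.size:
        raise ValueError(f"constant trait column(s): {[names[j] for j in const]}")
    return (Xm - means) / sds, means, sds


def _dummy_code(classes) -> tuple[np.ndarray, list]:
    classes = np.asarray(classes)
    levels = sorted(set(classes.tolist()))
    Y = np.array([[1.0 if c == lev else 0.0 for lev in levels] for c in classes])
    return Y, levels


@dataclass
class PLSDAModel:
    """Fitted two-block NIPALS PLS-DA model.

    Component matrices have one column per component: ``x_weights`` (w),
    ``x_loadings`` (p), ``y_loadings`` (c), ``scores`` (t, one row per
    plant). ``r2x_cum`` / ``r2y_cum`` are cumulative explained
    sum-of-squares fractions of the scaled X and dummy Y blocks.
    """

    n_components: int
    trait_names: list
    class_levels: list
    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    r2x: np.ndarray
    r2y: np.ndarray
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray
    y_sd: np.ndarray
    q2_cum: float = field(default=float("nan"))

    @property
    def r2x_cum(self) -> float:
        return float(self.r2x.sum())

    @property
    def r2y_cum(self) -> float:
        return float(self.r2y.sum())

    @property
    def vip(self) -> pd.Series:
        return vip(self)

    def coefficients(self) -> np.ndarray:
        """Regression coefficients B with Yhat_scaled = X_scaled @ B."""
        W, P, C = self.x_weights, self.x_loadings, self.y_loadings
        return W @ np.linalg.solve(P.T @ W, C.T)

    def predict_scores(self, X_new) -> np.ndarray:
        """Project new (raw) trait rows onto the fitted components."""
        Xm, _ = _as_matrix(X_new)
        Xs = (Xm - self.x_mean) / self.x_sd
        T = np.empty((len(Xs), self.n_components))
        for a in range(self.n_components):
            t = Xs @ self.x_weights[:, a]
            T[:, a] = t
            Xs = Xs - np.outer(t, self.x_loadings[:, a])
        return T


def _nipals(X: np.ndarray, Y: np.ndarray, n_components: int):
    """Core NIPALS PLS2 loop on pre-scaled blocks; returns W, P, C, T, r2x, r2y."""
    n, p = X.shape
    q = Y.shape[1]
    ssx0 = float((X ** 2).sum())
    ssy0 = float((Y ** 2).sum())
    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    C = np.empty((q, n_components))
    T = np.empty((n, n_components))
    r2x = np.empty(n_components)
    r2y = np.empty(n_components)
    for a in range(n_components):
        u = Y[:, int(np.argmax((Y ** 2).sum(axis=0)))].copy()
        t_old = None
        for _ in range(_MAX_ITER):
            w = X.T @ u / (u @ u)
            w /= np.linalg.norm(w)
            t = X @ w
            c = Y.T @ t / (t @ t)
            u = Y @ c / (c @ c)
            if t_old is not None and np.linalg.norm(t - t_old) <= _TOL * np.linalg.norm(t):
                break
            t_old = t
        else:
            raise RuntimeError(f"NIPALS did not converge for component {a + 1}")
        pa = X.T @ t / (t @ t)
        # sign convention: largest-|x_loading| entry positive, for reproducibility
        if pa[int(np.argmax(np.abs(pa)))] < 0:
            w, t, pa, c = -w, -t, -pa, -c
        X = X - np.outer(t, pa)
        Y = Y - np.outer(t, c)
        W[:, a], P[:, a], C[:, a], T[:, a] = w, pa, c, t
        r2x[a] = (t @ t) * (pa @ pa) / ssx0
        r2y[a] = (t @ t) * (c @ c) / ssy0
    return W, P, C, T, r2x, r2y


def plsda_fit(X, classes, n_components: int = 2) -> PLSDAModel:
    """Fit a PLS-DA model with NIPALS.

    Parameters
    ----------
    X : DataFrame or (n, p) array
        Trait matrix, no missing values, no constant columns.
    classes : sequence of length n
        Class label per plant; >= 2 classes with >= 2 members each.
    n_components : int
        Number of predictive components (2 matches the common two-component
        score-plot model); must not exceed rank(X).
    """
    Xm, names = _as_matrix(X)
    Xs, mx, sx = standardize(Xm if not isinstance(X, pd.DataFrame) else X)
    Y, levels = _dummy_code(classes)
    if len(levels) < 2:
        raise ValueError("PLS-DA needs >= 2 classes")
    counts = Y.sum(axis=0)
    small = [lev for lev, k in zip(levels, counts) if k < 2]
    if small:
        raise ValueError(f"class(es) with fewer than 2 members: {small}")
    if n_components > min(Xs.shape):
        raise ValueError(f"n_components={n_components} exceeds rank bound "
                         f"{min(Xs.shape)}")
    my = Y.mean(axis=0)
    sy = Y.std(axis=0, ddof=1)
    Ys = (Y - my) / sy
    W, P, C, T, r2x, r2y = _nipals(Xs.copy(), Ys.copy(), n_components)
    return PLSDAModel(n_components=n_components, trait_names=names,
                      class_levels=levels, x_weights=W, x_loadings=P,
                      y_loadings=C, scores=T, r2x=r2x, r2y=r2y,
                      x_mean=mx, x_sd=sx, y_mean=my, y_sd=sy)


def vip(model: PLSDAModel) -> pd.Series:
    """Variable importance in projection, one value per trait.

    VIP_j = sqrt( p * sum_a [ SSY_a * (w_ja / ||w_a||)^2 ] / sum_a SSY_a )
    where SSY_a is the Y sum of squares explained by component a. The mean
    of VIP^2 over traits is exactly 1, so VIP > 1 flags traits contributing
    more than average to class separation.
    """
    p = len(model.trait_names)
    ssy = model.r2y  # proportional to explained SSY per component
    W = model.x_weights
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    v = np.sqrt(p * (wn ** 2 @ ssy) / ssy.sum())
    return pd.Series(v, index=model.trait_names, name="vip")


def _stratified_folds(classes: np.ndarray, folds: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Fold index per sample; each class spread as evenly as possible."""
    assign = np.empty(len(classes), dtype=int)
    for lev in np.unique(classes):
        idx = np.where(classes == lev)[0]
        rng.shuffle(idx)
        assign[idx] = np.arange(len(idx)) % folds
    return assign


def q2_cv(X, classes, n_components: int = 2, folds: int = 7,
          seed: int = 0) -> float:
    """Cross-validated Q² of a PLS-DA model.

    Stratified k-fold CV (default 7 folds): each fold's plants are held
    out, the model is refit (including scaling) on the remainder, and the
    held-out dummy responses are predicted with the full ``n_components``
    model. Q²cum = 1 − PRESS / TSS on the centered, scaled dummy Y. The
    fold assignment is fixed by ``seed``, so results are reproducible.
    """
    Xm, _ = _as_matrix(X)
    cls = np.asarray(classes)
    levels = sorted(set(cls.tolist()))
    counts = {lev: int((cls == lev).sum()) for lev in levels}
    eff_folds = min(folds, min(counts.values()))
    if eff_folds < 2:
        raise ValueError("cross-validation needs every class to have >= 2 members")
    rng = np.random.default_rng(seed)
    assign = _stratified_folds(cls, eff_folds, rng)
    Yfull, _ = _dummy_code(cls)
    my = Yfull.mean(axis=0)
    sy = Yfull.std(axis=0, ddof=1)
    Ys = (Yfull - my) / sy
    press = 0.0
    for f in range(eff_folds):
        test = assign == f
        train = ~test
        model = plsda_fit(Xm[train], cls[train], n_components)
        Xs_test = (Xm[test] - model.x_mean) / model.x_sd
        Yhat_scaled = Xs_test @ model.coefficients()
        # back to the full-data scaled-Y frame for a comparable PRESS
        Yhat = Yhat_scaled * model.y_sd + model.y_mean
        press += float((((Yhat - my) / sy - Ys[test]) ** 2).sum())
    tss = float((Ys ** 2).sum())
    return 1.0 - press / tss


def permutation_test(X, classes, n_components: int = 2, folds: int = 7,
                     n_permutations: int = 1000, seed: int = 0) -> dict:
    """Label-permutation significance test for the cross-validated Q².

    Returns the observed Q², the permutation-null Q² values, and the
    one-sided p-value (fraction of permuted labelings with Q² at least as
    large, with the +1 continuity correction).
    """
    rng = np.random.default_rng(seed)
    cls = np.asarray(classes)
    observed = q2_cv(X, cls, n_components, folds, seed=int(rng.integers(2 ** 31)))
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(cls)
        null[i] = q2_cv(X, perm, n_components, folds,
                        seed=int(rng.integers(2 ** 31)))
    pval = (1 + int((null >= observed).sum())) / (n_permutations + 1)
    return {"q2": observed, "null": null, "p_value": pval}
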