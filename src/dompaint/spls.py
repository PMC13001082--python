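"""Sparse partial least squares (regression mode) for chemical-morphological
integration.

The model links a chemical abundance matrix X (samples x peaks) to
morphological profiles Y (samples x features) through shared latent
components. Each component solves

    max  cov(X u, Y v)   s.t.  ||u|| = ||v|| = 1,  u and v sparse,

by the NIPALS power iteration with lasso-style soft-thresholding of the
loading vectors to the ``keepX`` / ``keepY`` largest magnitudes
(renormalized to unit norm). Deflation is in regression mode: X is
deflated by its own scores, Y is regressed on the X scores, so the model
is directional (chemistry predicts morphology).

Model-size selection follows the cross-validated predictive index
Q2 = 1 - PRESS/RSS with the conventional 0.0975 retention threshold;
sparsity can be tuned by maximizing the cross-validated correlation of
the component-1 latent scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SplsModel",
    "CvSpec",
    "SplsConvergenceError",
    "Q2_THRESHOLD",
    "preprocess_xy",
    "fit_spls",
    "predict",
    "q2_total",
    "select_ncomponents",
    "tune_sparsity",
    "axis_feature_sets",
]

#: Conventional Q2 cutoff for retaining a latent component.
Q2_THRESHOLD = 0.0975


class SplsConvergenceError(RuntimeError):
    """NIPALS iteration failed to converge; carries iteration diagnostics."""

    def __init__(self, component: int, n_iter: int, delta: float):
        self.component = component
        self.n_iter = n_iter
        self.delta = delta
        super().__init__(
            f"sPLS component {component} did not converge in {n_iter} "
            f"iterations (last loading change {delta:.3e})"
        )


@dataclass
class CvSpec:
    """Cross-validation layout for Q2 and sparsity tuning."""

    folds: int = 10
    repeats: int = 5
    q2_threshold: float = Q2_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")

    def fold_assignments(self, n: int) -> np.ndarray:
        """(repeats, n) fold index array from a seeded shuffle."""
        if n < self.folds:
            raise ValueError(f"n={n} smaller than the number of folds {self.folds}")
        rng = np.random.default_rng(self.seed)
        base = np.arange(n) % self.folds
        out = np.empty((self.repeats, n), dtype=int)
        for r in range(self.repeats):
            out[r] = rng.permutation(base)
        return out


@dataclass
class SplsModel:
    """Fitted sparse PLS model (regression mode).

    Per component h (columns of the arrays): x-loading u_h and y-loading
    v_h (unit norm, sparse), x-scores xi_h and y-scores omega_h,
    deflation regressors c_h (X on xi) and d_h (Y on xi).
    """

    x_names: list[str]
    y_names: list[str]
    x_mean: np.ndarray
    y_mean: np.ndarray
    u: np.ndarray               # pX x ncomp
    v: np.ndarray               # pY x ncomp
    xi: np.ndarray              # n x ncomp (x-scores)
    omega: np.ndarray           # n x ncomp (y-scores)
    c: np.ndarray               # pX x ncomp (X deflation regressors)
    d: np.ndarray               # pY x ncomp (Y regression coefficients)
    var_explained_x: np.ndarray
    var_explained_y: np.ndarray
    q2: np.ndarray | None = None
    keepX: int | None = None
    keepY: int | None = None
    n_iterations: list[int] = field(default_factory=list)

    @property
    def ncomp(self) -> int:
        return self.u.shape[1]

    def selected_x(self, component: int = 1) -> list[str]:
        w = self.u[:, component - 1]
        return [self.x_names[i] for i in np.flatnonzero(w)]

    def selected_y(self, component: int = 1) -> list[str]:
        w = self.v[:, component - 1]
        return [self.y_names[i] for i in np.flatnonzero(w)]


def preprocess_xy(
    x_raw: pd.DataFrame,
    y_raw: pd.DataFrame,
    row_zscore: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Prepare matched chemical (X) and morphological (Y) blocks.

    X: TIC-normalize each sample row, drop zero-variance peak columns
    (logged), scale every remaining peak to unit variance across
    samples. Y is taken as given (per-sample median profiles). The two
    blocks are then concatenated and each sample row z-scored across the
    merged features, and re-split. Set ``row_zscore=False`` for the
    column-standardized-only variant.
    """
    common = x_raw.index.intersection(y_raw.index)
    only = set(x_raw.index).symmetric_difference(y_raw.index)
    if only:
        raise ValueError(f"samples present in only one block: {sorted(only)}")
    if len(common) < 3:
        raise ValueError("need at least 3 matched samples")
    x = x_raw.loc[common].astype(float)
    y = y_raw.loc[common].astype(float)

    totals = x.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("sample with zero total X intensity")
    x = x.div(totals, axis=0)

    sd = x.std(axis=0, ddof=1)
    keep = sd > 1e-12  # tolerance absorbs TIC-division float residue
    if (~keep).any():
        warnings.warn(f"dropping {(~keep).sum()} constant peak column(s) before scaling")
    x = x.loc[:, keep] / sd[keep]

    ysd = y.std(axis=0, ddof=1)
    if (ysd == 0).all():
        raise ValueError("Y has no variance")

    if row_zscore:
        merged = pd.concat([x, y], axis=1)
        mu = merged.mean(axis=1)
        sigma = merged.std(axis=1, ddof=0)
        if (sigma == 0).any():
            raise ValueError("constant merged row; cannot z-score by sample")
        merged = merged.sub(mu, axis=0).div(sigma, axis=0)
        x = merged.iloc[:, : x.shape[1]]
        y = merged.iloc[:, x.shape[1]:]
    return x, y


def _soft_threshold_keep(w: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold ``w`` so at most ``keep`` entries stay nonzero.

    The threshold is the (keep+1)-th largest |w| — the lasso shrinkage
    level that zeroes everything below the keep largest magnitudes.
    """
    p = w.size
    if keep >= p:
        return w.copy()
    lam = np.sort(np.abs(w))[p - keep - 1]
    return np.sign(w) * np.maximum(np.abs(w) - lam, 0.0)


def _fit_component(
    x: np.ndarray, y: np.ndarray, keepX: int, keepY: int,
    max_iter: int, tol: float, component: int,
) -> tuple[np.ndarray, np.ndarray, int]:
    m = x.T @ y                       # pX x pY cross-covariance
    dense = keepX >= x.shape[1] and keepY >= y.shape[1]
    # deterministic init from the dominant singular pair; with no
    # thresholding that pair already is the NIPALS fixed point
    uu, _, vt = np.linalg.svd(m, full_matrices=False)
    u, v = uu[:, 0], vt[0]
    it = 1
    if not dense:
        delta = np.inf
        for it in range(1, max_iter + 1):
            u_new = m @ v
            u_new = _soft_threshold_keep(u_new, keepX)
            nu = np.linalg.norm(u_new)
            if nu == 0:
                raise SplsConvergenceError(component, it, np.inf)
            u_new /= nu
            v_new = m.T @ u_new
            v_new = _soft_threshold_keep(v_new, keepY)
            nv = np.linalg.norm(v_new)
            if nv == 0:
                raise SplsConvergenceError(component, it, np.inf)
            v_new /= nv
            delta = max(np.max(np.abs(u_new - u)), np.max(np.abs(v_new - v)))
            u, v = u_new, v_new
            if delta < tol:
                break
        else:
            warnings.warn(
                f"sPLS component {component} stopped at the {max_iter}-iteration "
                f"cap (last loading change {delta:.2e})"
            )
    # sign convention: largest-|u| entry positive
    i = int(np.argmax(np.abs(u)))
    if u[i] < 0:
        u, v = -u, -v
    return u, v, it


def fit_spls(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    ncomp: int = 1,
    keepX: int | None = None,
    keepY: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> SplsModel:
    """Fit a regression-mode sparse PLS model.

    ``keepX`` / ``keepY`` bound the number of nonzero entries per
    loading vector (defaults: all features, i.e. dense PLS). Columns are
    mean-centered internally; scaling is the caller's concern
    (see :func:`preprocess_xy`).
    """
    if not X.index.equals(Y.index):
        raise ValueError("X and Y must be row-matched")
    pX, pY = X.shape[1], Y.shape[1]
    keepX = pX if keepX is None else keepX
    keepY = pY if keepY is None else keepY
    if not 1 <= keepX <= pX:
        raise ValueError(f"keepX must be in [1, {pX}]")
    if not 1 <= keepY <= pY:
        raise ValueError(f"keepY must be in [1, {pY}]")
    x = X.to_numpy(dtype=float)
    y = Y.to_numpy(dtype=float)
    if np.allclose(y.var(axis=0), 0):
        raise ValueError("Y has zero variance")
    x_mean = x.mean(axis=0)
    y_mean = y.mean(axis=0)
    x = x - x_mean
    y = y - y_mean
    ss_x0 = float((x**2).sum())
    ss_y0 = float((y**2).sum())

    n = x.shape[0]
    U = np.zeros((pX, ncomp))
    V = np.zeros((pY, ncomp))
    XI = np.zeros((n, ncomp))
    OM = np.zeros((n, ncomp))
    C = np.zeros((pX, ncomp))
    D = np.zeros((pY, ncomp))
    vex = np.zeros(ncomp)
    vey = np.zeros(ncomp)
    iters: list[int] = []

    for h in range(ncomp):
        u, v, it = _fit_component(x, y, keepX, keepY, max_iter, tol, h + 1)
        xi = x @ u
        om = y @ v
        denom = float(xi @ xi)
        if denom == 0:
            raise SplsConvergenceError(h + 1, it, 0.0)
        c = x.T @ xi / denom
        d = y.T @ xi / denom
        x = x - np.outer(xi, c)
        y = y - np.outer(xi, d)
        U[:, h], V[:, h], XI[:, h], OM[:, h], C[:, h], D[:, h] = u, v, xi, om, c, d
        vex[h] = denom * float(c @ c) / ss_x0 if ss_x0 > 0 else 0.0
        vey[h] = denom * float(d @ d) / ss_y0 if ss_y0 > 0 else 0.0
        iters.append(it)

    return SplsModel(
        x_names=list(X.columns), y_names=list(Y.columns),
        x_mean=x_mean, y_mean=y_mean,
        u=U, v=V, xi=XI, omega=OM, c=C, d=D,
        var_explained_x=vex, var_explained_y=vey,
        keepX=keepX, keepY=keepY, n_iterations=iters,
    )


def predict(model: SplsModel, X_new: pd.DataFrame | np.ndarray, ncomp: int | None = None) -> np.ndarray:
    """Predict Y for new samples from the first ``ncomp`` components."""
    ncomp = model.ncomp if ncomp is None else ncomp
    if not 0 <= ncomp <= model.ncomp:
        raise ValueError(f"ncomp must be in [0, {model.ncomp}]")
    x = np.asarray(X_new, dtype=float) - model.x_mean
    yhat = np.tile(model.y_mean, (x.shape[0], 1))
    if ncomp == 0:
        return yhat
    W = model.u[:, :ncomp]
    C = model.c[:, :ncomp]
    D = model.d[:, :ncomp]
    # scores of new data under sequential deflation: T = X W (C'W)^-1
    t = x @ W @ np.linalg.inv(C.T @ W)
    return yhat + t @ D.T


def q2_total(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    ncomp: int,
    keepX: int | None = None,
    keepY: int | None = None,
    cv: CvSpec | None = None,
) -> np.ndarray:
    """Cross-validated Q2.total per component.

    Q2_h = 1 - PRESS_h / RSS_{h-1}, where PRESS_h sums squared
    out-of-fold prediction errors of the h-component model over all Y
    columns, and RSS_{h-1} is the residual sum of squares of the
    (h-1)-component model fitted on the full data (RSS_0 = total sum of
    squares of Y about its column means). Values are averaged over the
    CV repeats. Centering is fold-wise: held-out rows never contribute
    to the training means.
    """
    cv = cv or CvSpec()
    n = len(X)
    folds = cv.fold_assignments(n)
    x_all = X.to_numpy(dtype=float)
    y_all = Y.to_numpy(dtype=float)

    # full-data residual sums of squares RSS_0 .. RSS_{ncomp-1}
    full = fit_spls(X, Y, ncomp=ncomp, keepX=keepX, keepY=keepY)
    rss = np.empty(ncomp)
    for h in range(ncomp):
        resid = y_all - predict(full, x_all, ncomp=h)
        rss[h] = float((resid**2).sum())

    q2_reps = np.zeros((cv.repeats, ncomp))
    for r in range(cv.repeats):
        press = np.zeros(ncomp)
        for f in range(cv.folds):
            test = folds[r] == f
            train = ~test
            if test.sum() < 1 or train.sum() < 2:
                raise ValueError("fold with too few samples")
            Xtr = X.iloc[train]
            Ytr = Y.iloc[train]
            model = fit_spls(Xtr, Ytr, ncomp=ncomp, keepX=keepX, keepY=keepY)
            for h in range(ncomp):
                pred = predict(model, x_all[test], ncomp=h + 1)
                press[h] += float(((y_all[test] - pred) ** 2).sum())
        q2_reps[r] = 1.0 - press / rss
    return q2_reps.mean(axis=0)


def select_ncomponents(q2: np.ndarray, threshold: float = Q2_THRESHOLD) -> int:
    """Number of leading components with Q2 above the threshold.

    Counting stops at the first component at or below the threshold. A
    result of 0 means no component has non-random predictive value.
    """
    q2 = np.asarray(q2, dtype=float)
    if q2.size == 0:
        raise ValueError("empty Q2 sequence")
    k = 0
    for val in q2:
        if val > threshold:
            k += 1
        else:
            break
    if k == 0:
        warnings.warn("no component exceeds the Q2 threshold; model not interpretable")
    return k


def tune_sparsity(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    grid: list[tuple[int, int]],
    cv: CvSpec | None = None,
) -> tuple[int, int]:
    """Pick (keepX, keepY) maximizing the cross-validated latent correlation.

    For each grid point the component-1 model is fitted on each training
    fold; held-out samples are projected (xi = X u, omega = Y v) and the
    Pearson correlation of the pooled out-of-fold scores is averaged
    over repeats. Ties break toward sparser keepX, then keepY.
    """
    if not grid:
        raise ValueError("empty sparsity grid")
    cv = cv or CvSpec()
    n = len(X)
    folds = cv.fold_assignments(n)
    x_all = X.to_numpy(dtype=float)
    y_all = Y.to_numpy(dtype=float)

    results: list[tuple[float, int, int]] = []
    for keepX, keepY in grid:
        rep_corrs = []
        degenerate = False
        for r in range(cv.repeats):
            t_oof = np.empty(n)
            w_oof = np.empty(n)
            for f in range(cv.folds):
                test = folds[r] == f
                train = ~test
                model = fit_spls(X.iloc[train], Y.iloc[train], ncomp=1,
                                 keepX=keepX, keepY=keepY)
                t_oof[test] = (x_all[test] - model.x_mean) @ model.u[:, 0]
                w_oof[test] = (y_all[test] - model.y_mean) @ model.v[:, 0]
            if np.std(t_oof) == 0 or np.std(w_oof) == 0:
                degenerate = True
                break
            rep_corrs.append(float(np.corrcoef(t_oof, w_oof)[0, 1]))
        if degenerate:
            warnings.warn(f"grid point keepX={keepX}, keepY={keepY} skipped: constant scores")
            continue
        results.append((float(np.mean(rep_corrs)), keepX, keepY))
    if not results:
        raise ValueError("every grid point was degenerate")
    best = max(results, key=lambda t: (t[0], -t[1], -t[2]))
    return best[1], best[2]


def axis_feature_sets(model: SplsModel, component: int = 1) -> dict[str, list[str]]:
    """Selected X features split by loading sign on a component.

    Returns {'negative': [...], 'positive': [...]}; zero loadings are
    unselected and appear in neither set.
    """
    if not 1 <= component <= model.ncomp:
        raise ValueError(f"component must be in [1, {model.ncomp}]")
    w = model.u[:, component - 1]
    return {
        "negative": [model.x_names[i] for i in np.flatnonzero(w < 0)],
        "positive": [model.x_names[i] for i in np.flatnonzero(w > 0)],
    }
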