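"""Sparse graph-reconstruction estimators and their tuning procedures.

Five estimators are provided, two correlation-based and three partial
correlation-based:

* ``hard_threshold`` — keep entries of a (sample) covariance or correlation
  matrix with ``|S_ij| > d``; with the scale-free criterion the threshold is
  chosen so the resulting degree distribution best fits a power law.
* ``covariance_lasso`` — sparse covariance estimation minimizing
  ``logdet(Sigma) + tr(Sigma^{-1} S) + lambda ||P o Sigma||_1`` by
  majorization-minimization: the concave ``logdet`` term is linearised at an
  anchor ``Sigma_0`` and the convex majorised problem is solved by proximal
  gradient descent.  The default performs the single majorization step at
  ``Sigma_0 = diag(S)``; additional MM sweeps re-anchor at the last iterate.
* ``nodewise_lasso`` — neighbourhood selection: lasso-regress each variable
  on the rest; an edge is present when the coefficient is nonzero under the
  AND/OR combination rule.  Coefficients relate to the precision matrix via
  ``beta^i_j = Theta_ij / Theta_ii``.
* ``graphical_lasso`` — L1-penalised precision estimation maximizing
  ``logdet(Theta) - tr(S Theta) - lambda ||Theta||_1`` (block coordinate
  descent via scikit-learn); output is symmetric PD, no combination rule
  needed.
* ``adaptive_lasso`` — two-stage nodewise regression whose second stage
  penalises each coefficient inversely to its first-stage magnitude; both
  penalties are chosen by K-fold cross-validation on prediction error.

Lasso objectives follow the ``(1/n)||y - Z b||_2^2 + lambda ||b||_1``
normalisation; scikit-learn's ``alpha`` equals ``lambda / 2`` under this
convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn import linear_model
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso
from sklearn.model_selection import KFold

from .graphs import WeightedGraph
from .synthetic import DataMatrix, SampleCovariance

__all__ = [
    "EstimateRecord",
    "ScaleFreeFit",
    "hard_threshold",
    "scale_free_scan",
    "select_threshold_scale_free",
    "covariance_lasso",
    "cv_covariance_lasso",
    "lasso_regression",
    "nodewise_lasso",
    "nodewise_lasso_path",
    "graphical_lasso",
    "adaptive_lasso",
    "lambda_max_nodewise",
    "default_lambda_grid",
    "SUPPORT_TOL",
]

#: zero tolerance for support extraction (entries below this, after scaling
#: to unit diagonal where applicable, are treated as absent edges)
SUPPORT_TOL = 1e-8


@dataclass
class EstimateRecord:
    """One estimator's output: weight matrix, binary graph, tuning value."""

    method: str
    estimate: np.ndarray
    graph: WeightedGraph
    param: float
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ScaleFreeFit:
    """Power-law fit of the degree distribution of a thresholded graph.

    ``log10 P(k) = -gamma_hat * log10 k + b_hat`` fitted by least squares
    over occupied positive-degree bins; ``R2`` is the goodness of fit and
    ``mean_degree`` the average (binary) degree.  ``R2``, ``gamma_hat`` and
    ``b_hat`` are NaN when fewer than two distinct bins exist.
    """

    threshold: float
    R2: float
    gamma_hat: float
    b_hat: float
    mean_degree: float
    n_bins: int = 0

    @property
    def valid(self) -> bool:
        return np.isfinite(self.R2)


def _support_graph(estimate: np.ndarray, tol: float = SUPPORT_TOL) -> WeightedGraph:
    adj = np.where(np.abs(estimate) > tol, estimate, 0.0)
    np.fill_diagonal(adj, 0.0)
    return WeightedGraph((adj + adj.T) / 2)


# ---------------------------------------------------------------------------
# Hard thresholding and the scale-free criterion

def hard_threshold(S: SampleCovariance | np.ndarray, d: float) -> EstimateRecord:
    """Keep off-diagonal entries with ``|S_ij| > d`` (absolute-value rule)."""
    if d < 0:
        raise ValueError("threshold must be nonnegative")
    M = S.S if isinstance(S, SampleCovariance) else np.asarray(S, dtype=float)
    est = M.copy()
    off = ~np.eye(len(M), dtype=bool)
    est[off & (np.abs(M) <= d)] = 0.0
    return EstimateRecord(
        method="thresh_cov", estimate=est, graph=_support_graph(est), param=d
    )


def _degree_distribution_fit(degrees: np.ndarray, threshold: float) -> ScaleFreeFit:
    p = len(degrees)
    mean_degree = float(degrees.mean())
    ks, counts = np.unique(degrees[degrees >= 1], return_counts=True)
    if len(ks) < 2:
        return ScaleFreeFit(threshold, np.nan, np.nan, np.nan, mean_degree, len(ks))
    x = np.log10(ks.astype(float))
    y = np.log10(counts / p)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    R2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else np.nan
    return ScaleFreeFit(
        threshold, float(R2), float(-slope), float(intercept), mean_degree, len(ks)
    )


def scale_free_scan(
    S: SampleCovariance | np.ndarray, grid: np.ndarray
) -> list[ScaleFreeFit]:
    """Fit the power-law degree model at every threshold of the grid."""
    M = S.S if isinstance(S, SampleCovariance) else np.asarray(S, dtype=float)
    out = []
    for d in np.asarray(grid, dtype=float):
        g = hard_threshold(M, d).graph
        degrees = (g.adjacency != 0).sum(axis=0)
        out.append(_degree_distribution_fit(degrees, float(d)))
    return out


def select_threshold_scale_free(
    scan: list[ScaleFreeFit],
    r2_min: float = 0.8,
    require_positive_gamma: bool = True,
    min_bins: int = 3,
) -> float:
    """Choose the threshold with the lowest mean degree among good fits.

    A fit qualifies when ``R2 >= r2_min``, (optionally) ``gamma_hat > 0``,
    and the degree distribution occupies at least ``min_bins`` distinct
    positive degrees — an affine fit through fewer points is degenerate
    (two points always give R^2 = 1).  Ties on mean degree resolve to the
    smallest threshold.
    """
    if not scan:
        raise ValueError("empty scan")
    ok = [
        f
        for f in scan
        if f.valid
        and f.n_bins >= min_bins
        and f.R2 >= r2_min
        and (f.gamma_hat > 0 or not require_positive_gamma)
    ]
    if not ok:
        best = max((f.R2 for f in scan if f.valid), default=np.nan)
        raise ValueError(
            f"no threshold passes R2 >= {r2_min} (best attained R2 = {best:.3f})"
        )
    return min(ok, key=lambda f: (f.mean_degree, f.threshold)).threshold


# ---------------------------------------------------------------------------
# Covariance lasso (majorization-minimization)

def _prox_step(
    X: np.ndarray,
    Theta0: np.ndarray,
    S: np.ndarray,
    lam: float,
    P: np.ndarray,
    max_inner: int,
    tol: float,
) -> tuple[np.ndarray, int]:
    """Proximal gradient descent on the majorised convex objective.

    Minimises ``tr(Theta0 Sigma) + tr(Sigma^{-1} S) + lam ||P o Sigma||_1``
    over PD matrices, with backtracking line search; the PD constraint is
    enforced by rejecting steps whose Cholesky fails.
    """
    I = np.eye(len(S))
    Xinv = linalg.cho_solve(linalg.cho_factor(X), I)
    hX = float(np.sum(Theta0 * X) + np.sum(Xinv * S))
    t = 1.0
    it = 0
    for it in range(1, max_inner + 1):
        G = Theta0 - Xinv @ S @ Xinv
        accepted = False
        for _ in range(40):
            Y = X - t * G
            Y = np.sign(Y) * np.maximum(np.abs(Y) - t * lam * P, 0.0)
            Y = (Y + Y.T) / 2
            try:
                c = linalg.cho_factor(Y)
            except linalg.LinAlgError:
                t *= 0.5
                continue
            Yinv = linalg.cho_solve(c, I)
            hY = float(np.sum(Theta0 * Y) + np.sum(Yinv * S))
            bound = hX + np.sum(G * (Y - X)) + np.sum((Y - X) ** 2) / (2 * t)
            if hY <= bound + 1e-12:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            break
        delta = float(np.max(np.abs(Y - X)))
        X, Xinv, hX = Y, Yinv, hY
        if delta < tol:
            break
        t *= 1.6
    return X, it


def _cov_lasso_objective(Sigma: np.ndarray, S: np.ndarray, lam: float, P: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return np.inf
    return float(logdet + np.trace(linalg.solve(Sigma, S)) + lam * np.abs(P * Sigma).sum())


def covariance_lasso(
    S: SampleCovariance | np.ndarray,
    lambda_cov: float,
    P: np.ndarray | None = None,
    Sigma0: np.ndarray | None = None,
    s_reg: float | None = None,
    n_samples: int | None = None,
    n_mm_steps: int = 1,
    max_inner: int = 500,
    tol: float = 1e-7,
) -> EstimateRecord:
    """Sparse covariance estimate by (majorised) penalised likelihood.

    Minimises ``logdet(Sigma) + tr(Sigma^{-1} S) + lambda_cov ||P o Sigma||_1``.
    The concave ``logdet`` is linearised at ``Sigma0`` (default ``diag(S)``)
    and the resulting convex problem solved by proximal gradient descent;
    with ``n_mm_steps > 1`` the anchor is re-set to the last iterate and the
    objective is non-increasing across sweeps.

    For rank-deficient input (p > n) a ridge ``s_reg * I`` is added to ``S``
    first (default ``1e-3 * mean(diag(S))`` when ``n_samples`` indicates
    p > n or when S is singular).
    """
    if lambda_cov < 0:
        raise ValueError("lambda_cov must be nonnegative")
    Smat = (S.S if isinstance(S, SampleCovariance) else np.asarray(S, dtype=float)).copy()
    p = Smat.shape[0]
    if s_reg is None:
        needs_reg = (n_samples is not None and n_samples < p) or (
            linalg.eigvalsh(Smat, subset_by_index=(0, 0))[0] < 1e-10
        )
        s_reg = 1e-3 * float(np.mean(np.diag(Smat))) if needs_reg else 0.0
    Smat += s_reg * np.eye(p)
    if P is None:
        P = np.ones((p, p)) - np.eye(p)
    Sigma = np.diag(np.diag(Smat)).copy() if Sigma0 is None else np.asarray(Sigma0, dtype=float).copy()
    objective = [_cov_lasso_objective(Sigma, Smat, lambda_cov, P)]
    inner_iters = []
    for _ in range(n_mm_steps):
        Theta0 = linalg.cho_solve(linalg.cho_factor(Sigma), np.eye(p))
        Sigma, used = _prox_step(Sigma, Theta0, Smat, lambda_cov, P, max_inner, tol)
        inner_iters.append(used)
        objective.append(_cov_lasso_objective(Sigma, Smat, lambda_cov, P))
        if objective[-2] - objective[-1] < 1e-8 * max(abs(objective[-2]), 1.0):
            break
    converged = inner_iters[-1] < max_inner
    if not converged:
        warnings.warn("covariance lasso inner solver hit max_inner", RuntimeWarning)
    return EstimateRecord(
        method="cov_lasso",
        estimate=Sigma,
        graph=_support_graph(Sigma),
        param=lambda_cov,
        meta={
            "objective": objective,
            "inner_iterations": inner_iters,
            "converged": converged,
            "s_reg": s_reg,
        },
    )


def _gaussian_loglik(Sigma: np.ndarray, S_val: np.ndarray) -> float:
    """Unpenalised Gaussian log-likelihood (up to constants): -logdet - tr."""
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return -np.inf
    return float(-logdet - np.trace(linalg.solve(Sigma, S_val)))


def cv_covariance_lasso(
    X: DataMatrix | np.ndarray,
    grid: np.ndarray,
    K: int = 5,
    seed: int | None = None,
    **fit_kwargs,
) -> tuple[float, np.ndarray]:
    """K-fold cross-validated penalty for the covariance lasso.

    Fits on training folds, scores the unpenalised Gaussian log-likelihood
    on each validation fold's sample covariance, and returns the maximiser
    together with the CV curve (mean log-likelihood per grid value).
    """
    Xm = X.X if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
    n = Xm.shape[0]
    grid = np.asarray(grid, dtype=float)
    if K < 2:
        raise ValueError("need K >= 2 folds")
    if n < 2 * K:
        raise ValueError(f"folds of n={n}/{K} too small to form a covariance")
    kf = KFold(n_splits=K, shuffle=True, random_state=seed)
    scores = np.zeros((K, len(grid)))
    for f, (tr, va) in enumerate(kf.split(Xm)):
        S_tr = Xm[tr].T @ Xm[tr] / len(tr)
        S_va = Xm[va].T @ Xm[va] / len(va)
        for gi, lam in enumerate(grid):
            rec = covariance_lasso(S_tr, lam, n_samples=len(tr), **fit_kwargs)
            scores[f, gi] = _gaussian_loglik(rec.estimate, S_va)
    curve = scores.mean(axis=0)
    return float(grid[int(np.argmax(curve))]), curve


# ---------------------------------------------------------------------------
# Lasso regressions (nodewise / adaptive)

def lasso_regression(
    y: np.ndarray,
    Z: np.ndarray,
    lam: float,
    weights: np.ndarray | None = None,
    max_iter: int = 5000,
    tol: float = 1e-6,
) -> np.ndarray:
    """Lasso under the ``(1/n)||y - Z b||^2 + lam * sum_j w_j |b_j|`` objective.

    The weighted penalty is absorbed by column rescaling ``Z_j / w_j``;
    coefficients with ``w_j = inf`` are excluded (forced to zero).  With
    ``lam = 0`` the ordinary least-squares solution is returned.
    """
    y = np.asarray(y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if lam < 0:
        raise ValueError("penalty must be nonnegative")
    if lam == 0:
        coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
        return coef
    if weights is None:
        scale = np.ones(Z.shape[1])
        active = np.ones(Z.shape[1], dtype=bool)
    else:
        weights = np.asarray(weights, dtype=float)
        active = np.isfinite(weights) & (weights > 0)
        scale = np.where(active, 1.0 / np.where(active, weights, 1.0), 0.0)
    beta = np.zeros(Z.shape[1])
    if active.any():
        model = linear_model.Lasso(
            alpha=lam / 2, fit_intercept=False, max_iter=max_iter, tol=tol
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Z[:, active] * scale[active], y)
        beta[active] = model.coef_ * scale[active]
    return beta


def lambda_max_nodewise(X: np.ndarray) -> float:
    """Smallest penalty at which every nodewise lasso solution is zero.

    From the KKT conditions at zero: ``lam_max = max_i max_j |2 Z^T y / n|``
    over the p regressions.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    G = 2 * np.abs(X.T @ X) / n
    np.fill_diagonal(G, 0.0)
    return float(G.max())


def default_lambda_grid(X: np.ndarray, num: int = 50, ratio: float = 1e-3) -> np.ndarray:
    """Log-spaced penalty grid from ``lambda_max`` down to ``ratio*lambda_max``."""
    lmax = lambda_max_nodewise(X)
    return np.geomspace(lmax, ratio * lmax, num)


def nodewise_lasso_path(
    X: DataMatrix | np.ndarray, grid: np.ndarray, max_iter: int = 3000
) -> np.ndarray:
    """Coefficient cube ``B[g, i, j]`` of every nodewise lasso on a grid.

    ``B[g, i, j]`` is the coefficient of node j in the regression of node i
    at penalty ``grid[g]``.  Computed with one coordinate-descent path per
    node (warm starts across the grid).
    """
    Xm = X.X if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
    n, p = Xm.shape
    grid = np.asarray(grid, dtype=float)
    order = np.argsort(-grid)  # sklearn wants descending alphas
    alphas = grid[order] / 2
    B = np.zeros((len(grid), p, p))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(p):
            idx = np.concatenate([np.arange(i), np.arange(i + 1, p)])
            _, coefs, _ = linear_model.lasso_path(
                Xm[:, idx], Xm[:, i], alphas=alphas, max_iter=max_iter
            )
            B[order[:, None], i, idx[None, :]] = coefs.T
    return B


def _combine_rule(B: np.ndarray, rule: str) -> tuple[np.ndarray, np.ndarray]:
    """Combine the two per-edge coefficients into a support and weight matrix."""
    nz = B != 0
    if rule == "and":
        support = nz & nz.T
    elif rule == "or":
        support = nz | nz.T
    else:
        raise ValueError(f"rule must be 'and' or 'or', got {rule!r}")
    weight = np.where(support, (B + B.T) / 2, 0.0)
    np.fill_diagonal(weight, 0.0)
    return support, weight


def nodewise_lasso(
    X: DataMatrix | np.ndarray,
    lambda_L: float,
    rule: str = "or",
    max_iter: int = 5000,
) -> EstimateRecord:
    """Neighbourhood selection: one lasso regression per node.

    Edge (i, j) is present iff ``beta^i_j != 0`` AND/OR ``beta^j_i != 0``;
    the stored weight is the average of the two coefficients.
    """
    Xm = X.X if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
    p = Xm.shape[1]
    B = np.zeros((p, p))
    for i in range(p):
        idx = np.concatenate([np.arange(i), np.arange(i + 1, p)])
        B[i, idx] = lasso_regression(Xm[:, i], Xm[:, idx], lambda_L, max_iter=max_iter)
    _, weight = _combine_rule(B, rule)
    return EstimateRecord(
        method="nodewise",
        estimate=weight,
        graph=_support_graph(weight, tol=0.0),
        param=lambda_L,
        meta={"rule": rule, "B": B},
    )


# ---------------------------------------------------------------------------
# Graphical lasso

def graphical_lasso(
    S: SampleCovariance | np.ndarray,
    lambda_G: float,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> EstimateRecord:
    """L1-penalised precision estimation (block coordinate descent).

    Maximises ``logdet(Theta) - tr(S Theta) - lambda_G ||Theta||_1`` (the
    penalty acting on off-diagonal entries); the estimate is symmetric PD.
    """
    if lambda_G <= 0:
        raise ValueError("lambda_G must be positive (required when p > n)")
    Smat = S.S if isinstance(S, SampleCovariance) else np.asarray(S, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cov, prec = _sk_graphical_lasso(Smat, alpha=lambda_G, max_iter=max_iter, tol=tol)
    prec = (prec + prec.T) / 2
    return EstimateRecord(
        method="glasso",
        estimate=prec,
        graph=_support_graph(prec, tol=SUPPORT_TOL * float(np.max(np.abs(prec)))),
        param=lambda_G,
        meta={"covariance": cov},
    )


# ---------------------------------------------------------------------------
# Adaptive lasso (two-stage nodewise regression)

def _cv_mse_nodewise(
    Xm: np.ndarray,
    grid: np.ndarray,
    K: int,
    seed: int | None,
    weights: np.ndarray | None = None,
) -> float:
    """Global CV penalty: mean held-out MSE summed over the p regressions.

    ``weights`` is an optional ``p x p`` matrix of per-coefficient penalty
    weights (rows = response node), as used by the adaptive second stage.
    """
    n, p = Xm.shape
    kf = KFold(n_splits=K, shuffle=True, random_state=seed)
    err = np.zeros(len(grid))
    for tr, va in kf.split(Xm):
        for i in range(p):
            idx = np.concatenate([np.arange(i), np.arange(i + 1, p)])
            w = weights[i, idx] if weights is not None else None
            if w is not None and not (np.isfinite(w) & (w > 0)).any():
                err += np.mean(Xm[va][:, i] ** 2)
                continue
            for gi, lam in enumerate(grid):
                beta = lasso_regression(
                    Xm[tr][:, i], Xm[tr][:, idx], lam, weights=w, max_iter=2000
                )
                resid = Xm[va][:, i] - Xm[va][:, idx] @ beta
                err[gi] += np.mean(resid**2)
    best = int(np.argmin(err))
    return float(grid[best])


def adaptive_lasso(
    X: DataMatrix | np.ndarray,
    lambda_grid: np.ndarray | None = None,
    K: int = 5,
    rule: str = "or",
    seed: int | None = None,
) -> EstimateRecord:
    """Two-stage adaptive nodewise lasso with CV-selected penalties.

    Stage 1 runs plain nodewise lasso at a cross-validated penalty; stage 2
    re-fits each regression with per-coefficient weights ``1/|beta_1|`` and a
    second cross-validated penalty.  Coefficients that stage 1 sets to zero
    are excluded from the stage-2 design, so the final support is nested in
    the stage-1 support.
    """
    Xm = X.X if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
    n, p = Xm.shape
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(Xm, num=25, ratio=1e-2)
    lam1 = _cv_mse_nodewise(Xm, lambda_grid, K, seed)
    stage1 = nodewise_lasso(Xm, lam1, rule=rule)
    B1 = stage1.meta["B"]
    with np.errstate(divide="ignore"):
        W = np.where(B1 != 0, 1.0 / np.abs(B1), np.inf)
    lam2 = _cv_mse_nodewise(Xm, lambda_grid, K, seed, weights=W)
    B2 = np.zeros((p, p))
    for i in range(p):
        idx = np.concatenate([np.arange(i), np.arange(i + 1, p)])
        B2[i, idx] = lasso_regression(Xm[:, i], Xm[:, idx], lam2, weights=W[i, idx])
    _, weight = _combine_rule(B2, rule)
    return EstimateRecord(
        method="adaptive",
        estimate=weight,
        graph=_support_graph(weight, tol=0.0),
        param=lam2,
        meta={"rule": rule, "lambda_stage1": lam1, "B": B2, "B_stage1": B1,
              "graph_stage1": stage1.graph},
    )
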