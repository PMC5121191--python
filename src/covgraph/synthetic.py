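"""Synthetic data from graph topologies.

The workflow turns a binary concentration-graph structure into a Gaussian
model and samples from it:

1. scale the adjacency, ``wA``, and shift the diagonal to make it positive
   definite: ``A_hat = wA + gamma*I`` with ``gamma = |min eigenvalue| + eps``;
2. invert and standardise to a correlation matrix
   ``C = Lambda^{-1} A_hat^{-1} Lambda^{-1}``;
3. factor ``C = U^T U`` (Cholesky) and draw ``X = R U`` with ``R`` an
   ``n x p`` standard-normal matrix, so rows of ``X`` are i.i.d. ``N(0, C)``.

Because ``A_hat`` plays the role of the precision matrix up to diagonal
scaling, the concentration graph of the sampled data is exactly the input
graph.  The edge-weight scalar ``w`` controls the overall correlation
magnitude, summarised by ``sigma = sqrt(var(C_ij))`` over all p^2 entries;
:func:`calibrate_weight` inverts that map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.optimize import brentq

from .graphs import WeightedGraph

__all__ = [
    "PDTransformParams",
    "CovarianceModel",
    "DataMatrix",
    "SampleCovariance",
    "pd_from_adjacency",
    "correlation_from_graph",
    "correlation_strength",
    "calibrate_weight",
    "sample_data",
    "sample_covariance",
    "CalibrationError",
]


class CalibrationError(ValueError):
    """Requested correlation strength is outside the achievable range."""


@dataclass(frozen=True)
class PDTransformParams:
    """Parameters of the positive-definite lift ``wA + gamma*I``."""

    w: float
    eps: float
    gamma: float


@dataclass(frozen=True)
class CovarianceModel:
    """Covariance-side objects: Sigma, its correlation C, diagonal scale Lambda.

    ``C = Lambda^{-1} Sigma Lambda^{-1}`` with ``Lambda_ii = sqrt(Sigma_ii)``.
    """

    Sigma: np.ndarray
    C: np.ndarray
    Lambda: np.ndarray

    @property
    def p(self) -> int:
        return self.Sigma.shape[0]


@dataclass(frozen=True)
class DataMatrix:
    """``n x p`` matrix of observations; rows are i.i.d. samples."""

    X: np.ndarray

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class SampleCovariance:
    """Sample covariance ``S = X^T X / n`` (PSD, rank <= min(n, p))."""

    S: np.ndarray

    @property
    def p(self) -> int:
        return self.S.shape[0]

    def to_correlation(self) -> np.ndarray:
        """Sample correlation: scale S to unit diagonal."""
        d = np.sqrt(np.diag(self.S))
        if np.any(d <= 0):
            raise ValueError("zero-variance column; correlation undefined")
        return self.S / np.outer(d, d)


def pd_from_adjacency(
    g: WeightedGraph, w: float = 0.5, eps: float = 0.1
) -> tuple[np.ndarray, PDTransformParams]:
    """Lift an adjacency matrix to a positive-definite matrix ``wA + gamma*I``.

    ``gamma = |min_i lambda_i(wA)| + eps`` guarantees the smallest eigenvalue
    is at least ``eps``.
    """
    if w <= 0 or eps <= 0:
        raise ValueError("w and eps must be positive")
    wA = w * g.adjacency
    ev_min = linalg.eigvalsh(wA, subset_by_index=(0, 0))[0]
    gamma = abs(min(ev_min, 0.0)) + eps
    A_hat = wA + gamma * np.eye(g.p)
    return A_hat, PDTransformParams(w=w, eps=eps, gamma=float(gamma))


def correlation_from_graph(
    g: WeightedGraph, w: float = 0.5, eps: float = 0.1
) -> CovarianceModel:
    """Build the Gaussian model whose concentration graph is ``g``.

    Inverts the positive-definite lift and standardises: ``Sigma = A_hat^-1``,
    ``C = Lambda^-1 Sigma Lambda^-1``.  The sparsity pattern of ``A_hat``
    (hence of ``g``) is exactly the off-diagonal support of ``C^-1``.
    """
    A_hat, _ = pd_from_adjacency(g, w=w, eps=eps)
    try:
        c, low = linalg.cho_factor(A_hat)
    except linalg.LinAlgError as e:  # pragma: no cover - construction is PD
        raise linalg.LinAlgError(f"positive-definite lift failed: {e}") from e
    Sigma = linalg.cho_solve((c, low), np.eye(g.p))
    Sigma = (Sigma + Sigma.T) / 2
    lam = np.sqrt(np.diag(Sigma))
    C = Sigma / np.outer(lam, lam)
    np.fill_diagonal(C, 1.0)
    return CovarianceModel(Sigma=Sigma, C=C, Lambda=np.diag(lam))


def correlation_strength(model: CovarianceModel) -> float:
    """Correlation magnitude ``sigma = sqrt(var(C_ij))`` over all p^2 entries.

    Population variance over the full matrix, diagonal included.  For C = I
    this tends to sqrt((p-1))/p as p grows (the identity-pattern floor).
    """
    return float(np.sqrt(model.C.var()))


def calibrate_weight(
    g: WeightedGraph,
    sigma_target: float,
    eps: float = 0.1,
    tol: float = 0.005,
    bracket: tuple[float, float] = (0.01, 5.0),
) -> float:
    """Find the edge weight ``w`` whose model has correlation strength
    ``sigma_target``.

    The strength is monotone increasing in ``w`` on the bracket, so a root
    of ``sigma(w) - sigma_target`` is found by Brent's method.

    Raises
    ------
    CalibrationError
        If the target lies outside the achievable ``[sigma_min, sigma_max]``
        on the bracket.
    """
    lo, hi = bracket

    def strength(w: float) -> float:
        return correlation_strength(correlation_from_graph(g, w=w, eps=eps))

    s_lo, s_hi = strength(lo), strength(hi)
    if not (min(s_lo, s_hi) - tol <= sigma_target <= max(s_lo, s_hi) + tol):
        raise CalibrationError(
            f"sigma_target={sigma_target} outside achievable range "
            f"[{min(s_lo, s_hi):.4f}, {max(s_lo, s_hi):.4f}] for w in {bracket}"
        )
    if abs(s_lo - sigma_target) <= tol and s_lo >= sigma_target:
        return lo
    if abs(s_hi - sigma_target) <= tol and s_hi <= sigma_target:
        return hi
    w = brentq(lambda w: strength(w) - sigma_target, lo, hi, xtol=1e-5)
    achieved = strength(w)
    if abs(achieved - sigma_target) > tol:
        raise CalibrationError(
            f"calibration landed at sigma={achieved:.4f}, "
            f"outside tol={tol} of target {sigma_target}"
        )
    return float(w)


def sample_data(
    model: CovarianceModel,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> DataMatrix:
    """Draw ``n`` i.i.d. samples from ``N(0, C)`` via the Cholesky factor.

    ``X = R U`` with ``C = U^T U`` (upper-triangular ``U``) and ``R`` an
    ``n x p`` standard-normal matrix.
    """
    rng = np.random.default_rng(seed)
    try:
        U = linalg.cholesky(model.C, lower=False)
    except linalg.LinAlgError as e:
        raise linalg.LinAlgError(f"correlation matrix not PD: {e}") from e
    R = rng.standard_normal((n, model.p))
    return DataMatrix(X=R @ U)


def sample_covariance(data: DataMatrix, center: bool = False) -> SampleCovariance:
    """``S = X^T X / n`` (divisor n; the model mean is known to be zero).

    With ``center=True`` column means are subtracted first (for real data);
    the divisor stays ``n``.
    """
    X = data.X
    if X.shape[0] < 1:
        raise ValueError("need at least one observation")
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    S = X.T @ X / X.shape[0]
    return SampleCovariance(S=(S + S.T) / 2)
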