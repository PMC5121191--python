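"""Network deconvolution: stripping indirect (transitive) edge contributions.

An observation matrix ``Sigma_M`` is modelled as the transitive closure of an
unknown direct-edge matrix ``A``:

    Sigma_M = A(I - A)^{-1} = A + A^2 + A^3 + ...

Deconvolution inverts this: ``A = Sigma_M(I + Sigma_M)^{-1}``; the scaled
variant ``A~ = alpha Sigma_M (I + alpha Sigma_M)^{-1}`` introduces a scaling
parameter controlling convergence of the inversion.  In practice the
observation matrix is used with a zero diagonal, although a true closure has
nonzero diagonal entries (cyclic walks); the adapted operator restores
exactness by re-injecting the closure diagonal ``V = diag(A*)``, and its
support coincides with the plain operator's.

For a chain whose k-th order indirect weights satisfy the product relation
``S_k = alpha^{k-1} theta^k``, the matrix ``I + alpha Sigma_M`` is the
Kac-Murdock-Szego (symmetric Toeplitz) matrix ``B_ij = (alpha theta)^|i-j|``
with a closed-form tridiagonal inverse, and deconvolution returns an exactly
tridiagonal (chain) matrix.  Particular alpha values can instead annihilate a
*direct* edge: for the 4-node chain the roots of a quadratic in alpha zero
the (1,2) entry, a failure mode of the method.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import linalg

from .graphs import WeightedGraph

__all__ = [
    "ObservationMatrix",
    "ChainModelParams",
    "deconvolve",
    "deconvolve_adapted",
    "chain_observation",
    "kms_matrix",
    "kms_inverse",
    "deconvolve_chain",
    "alpha_killing_edge",
    "observation_4node",
    "discriminative_ratio",
    "alpha_sweep",
    "edge_orders",
]


@dataclass(frozen=True)
class ObservationMatrix:
    """Symmetric observation matrix with a zero diagonal."""

    Sigma_M: np.ndarray

    def __post_init__(self) -> None:
        M = np.asarray(self.Sigma_M, dtype=float)
        if not np.allclose(M, M.T):
            raise ValueError("observation matrix must be symmetric")
        if np.any(np.diag(M) != 0):
            raise ValueError("observation matrix must have a zero diagonal")
        object.__setattr__(self, "Sigma_M", M)

    @property
    def p(self) -> int:
        return self.Sigma_M.shape[0]

    @classmethod
    def from_matrix(cls, M: np.ndarray) -> "ObservationMatrix":
        """Zero the diagonal of a symmetric matrix (the practical convention)."""
        M = np.asarray(M, dtype=float).copy()
        np.fill_diagonal(M, 0.0)
        return cls(Sigma_M=(M + M.T) / 2)


@dataclass(frozen=True)
class ChainModelParams:
    """Chain observation model: direct weight theta, scaling alpha.

    k-th order indirect weights are ``S_k = alpha^(k-1) theta^k``; the KMS
    normaliser is ``W = 1/(1 - alpha^2 theta^2)``.  Requires ``|theta| < 1``
    and ``|alpha*theta| < 1``.
    """

    theta: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if abs(self.theta) >= 1:
            raise ValueError(f"|theta| must be < 1, got {self.theta}")
        if abs(self.alpha * self.theta) >= 1:
            raise ValueError(
                f"|alpha*theta| = {abs(self.alpha * self.theta):.4f} >= 1; diverges"
            )

    @property
    def W(self) -> float:
        return 1.0 / (1.0 - (self.alpha * self.theta) ** 2)

    def s_k(self, k: int) -> float:
        """Indirect weight of order k >= 1 (k = 1 is the direct edge theta)."""
        return self.alpha ** (k - 1) * self.theta**k


def deconvolve(obs: ObservationMatrix | np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Scaled network deconvolution ``A~ = alpha Sigma_M (I + alpha Sigma_M)^{-1}``.

    alpha = 1 is the plain operator; applied to an exact closure
    ``A(I - A)^{-1}`` (diagonal included) it recovers ``A`` entrywise.
    Raises on a singular ``I + alpha Sigma_M`` — the failure mode of
    rank-deficient (p > n) sample covariances.  Accepts either the
    zero-diagonal :class:`ObservationMatrix` or a raw symmetric matrix.
    """
    M = obs.Sigma_M if isinstance(obs, ObservationMatrix) else np.asarray(obs, dtype=float)
    I = np.eye(M.shape[0])
    B = I + alpha * M
    if abs(np.linalg.det(B)) < 1e-12 or np.linalg.cond(B) > 1e12:
        raise np.linalg.LinAlgError(
            "I + alpha*Sigma_M is (numerically) singular; deconvolution "
            "needs a full-rank observation (fails for p > n without "
            "regularisation)"
        )
    # A~ = alpha M B^{-1}; solve B^T X^T = alpha M^T
    A = linalg.solve(B.T, (alpha * M).T).T
    return (A + A.T) / 2


def deconvolve_adapted(obs: ObservationMatrix, V: np.ndarray) -> np.ndarray:
    """Exact deconvolution for the zero-diagonal convention.

    With ``Sigma_M = A* - V`` and ``V = diag(A*)`` the direct-edge matrix is
    recovered exactly: ``A = (Sigma_M + V)(I + V + Sigma_M)^{-1}``.  The
    support equals that of :func:`deconvolve` at alpha = 1.
    """
    M = obs.Sigma_M if isinstance(obs, ObservationMatrix) else np.asarray(obs, dtype=float)
    V = np.asarray(V, dtype=float)
    if V.ndim == 1:
        V = np.diag(V)
    B = np.eye(M.shape[0]) + V + M
    if np.linalg.cond(B) > 1e12:
        raise np.linalg.LinAlgError("I + V + Sigma_M is numerically singular")
    A = linalg.solve(B.T, (M + V).T).T
    return (A + A.T) / 2


def chain_observation(p: int, params: ChainModelParams) -> ObservationMatrix:
    """Chain observation matrix with product-rule indirect weights.

    ``(Sigma_M)_ij = alpha^(|i-j|-1) theta^|i-j|`` off the diagonal.
    """
    k = np.abs(np.subtract.outer(np.arange(p), np.arange(p)))
    k_safe = k.copy()
    np.fill_diagonal(k_safe, 1)  # avoid alpha**(-1); diagonal is zeroed below
    M = params.alpha ** (k_safe - 1) * params.theta**k_safe
    np.fill_diagonal(M, 0.0)
    return ObservationMatrix(Sigma_M=M.astype(float))


def kms_matrix(p: int, params: ChainModelParams) -> np.ndarray:
    """Kac-Murdock-Szego matrix ``B_ij = (alpha theta)^|i-j|`` = I + alpha*Sigma_M."""
    r = params.alpha * params.theta
    k = np.abs(np.subtract.outer(np.arange(p), np.arange(p)))
    return r ** k.astype(float)


def kms_inverse(p: int, params: ChainModelParams) -> np.ndarray:
    """Closed-form tridiagonal inverse of the KMS matrix.

    Corners ``W``, interior diagonal ``W(1 + r^2)``, off-diagonal ``-W r``
    with ``r = alpha*theta`` and ``W = 1/(1 - r^2)``.
    """
    r = params.alpha * params.theta
    W = params.W
    Binv = np.zeros((p, p))
    idx = np.arange(p)
    Binv[idx, idx] = W * (1 + r**2)
    Binv[0, 0] = Binv[-1, -1] = W
    Binv[idx[:-1], idx[:-1] + 1] = -W * r
    Binv[idx[:-1] + 1, idx[:-1]] = -W * r
    return Binv


def deconvolve_chain(p: int, params: ChainModelParams) -> np.ndarray:
    """Closed-form deconvolution of the chain observation: a tridiagonal matrix.

    ``A~ = alpha Sigma_M B^{-1}`` with off-diagonal ``W alpha theta``, corner
    diagonal ``-W (alpha theta)^2`` and interior diagonal ``-2W (alpha theta)^2``.
    """
    r = params.alpha * params.theta
    W = params.W
    A = np.zeros((p, p))
    idx = np.arange(p)
    A[idx, idx] = -2 * W * r**2
    A[0, 0] = A[-1, -1] = -W * r**2
    A[idx[:-1], idx[:-1] + 1] = W * r
    A[idx[:-1] + 1, idx[:-1]] = W * r
    return A


def alpha_killing_edge(
    theta: tuple[float, float, float], s: tuple[float, float, float]
) -> list[float]:
    """Scaling values that annihilate the first direct edge of a 4-node chain.

    The observation matrix has direct weights ``theta = (theta1, theta2,
    theta3)`` on the chain 1-2-3-4 and free indirect weights ``s = (s1, s2,
    s3)`` at positions (1,3), (1,4), (2,4).  The deconvolved (1,2) entry
    vanishes at the real roots of

        M alpha^2 - (theta2*s1 + s2*s3) alpha + theta1 = 0,
        M = -theta1*theta3^2 + theta2*theta3*s2 + theta3*s1*s3.

    Returns the real roots (empty if the discriminant is negative); the
    degenerate linear case (M = 0) is handled.
    """
    th1, th2, th3 = theta
    s1, s2, s3 = s
    M = -th1 * th3**2 + th2 * th3 * s2 + th3 * s1 * s3
    b = th2 * s1 + s2 * s3
    scale = max(abs(th1), abs(th2), abs(th3), abs(s1), abs(s2), abs(s3), 1e-30)
    if abs(M) < 1e-12 * scale**3:  # degenerate: the quadratic collapses
        if abs(b) < 1e-12 * scale**2:
            return []
        return [th1 / b]
    disc = b**2 - 4 * th1 * M
    if disc < 0:
        return []
    root = np.sqrt(disc)
    return sorted({(b + root) / (2 * M), (b - root) / (2 * M)})


def observation_4node(
    theta: tuple[float, float, float], s: tuple[float, float, float]
) -> ObservationMatrix:
    """4-node chain observation with free direct and indirect weights."""
    th1, th2, th3 = theta
    s1, s2, s3 = s
    M = np.array(
        [
            [0.0, th1, s1, s2],
            [th1, 0.0, th2, s3],
            [s1, th2, 0.0, th3],
            [s2, s3, th3, 0.0],
        ]
    )
    return ObservationMatrix(Sigma_M=M)


def edge_orders(g_true: WeightedGraph) -> np.ndarray:
    """Shortest-path distance between every pair in the true graph.

    Order 1 pairs are direct edges; order k >= 2 pairs are indirect edges of
    order k.  Disconnected pairs get order 0 (excluded from ratio classes).
    """
    G = g_true.to_networkx()
    p = g_true.p
    orders = np.zeros((p, p), dtype=int)
    for i, dists in nx.all_pairs_shortest_path_length(G):
        for j, d in dists.items():
            orders[i, j] = d
    return orders


def discriminative_ratio(
    A_tilde: np.ndarray,
    obs: ObservationMatrix,
    g_true: WeightedGraph,
    order: int,
) -> float:
    """Log ratio of direct/indirect weight separation after vs before
    deconvolution, for indirect edges of a given order.

        r = log[ (<|A~_dir|>/<|A~_indir,k|>) / (<|Sigma_M,dir|>/<|Sigma_M,indir,k|>) ]

    Averages are over absolute weights of all pairs in each class.  Returns
    +inf when deconvolution exactly zeroes the indirect class, -inf when it
    zeroes the direct class; raises if a class is empty or the observation
    averages vanish.
    """
    if order < 2:
        raise ValueError("indirect order must be >= 2")
    orders = edge_orders(g_true)
    iu = np.triu_indices(g_true.p, 1)
    direct = orders[iu] == 1
    indirect = orders[iu] == order
    if not direct.any() or not indirect.any():
        raise ValueError(f"no pairs of order {order} (or no direct edges)")
    a_dir = np.abs(A_tilde[iu][direct]).mean()
    a_ind = np.abs(A_tilde[iu][indirect]).mean()
    m_dir = np.abs(obs.Sigma_M[iu][direct]).mean()
    m_ind = np.abs(obs.Sigma_M[iu][indirect]).mean()
    if m_dir == 0 or m_ind == 0:
        raise ValueError("observation matrix has a zero-average class")
    zero = 1e-12 * max(a_dir, a_ind, 1e-300)  # numerical zero for a class
    if a_ind <= zero:
        return np.inf if a_dir > zero else np.nan
    if a_dir <= zero:
        return -np.inf
    return float(np.log((a_dir / a_ind) / (m_dir / m_ind)))


def alpha_sweep(
    obs: ObservationMatrix,
    g_true: WeightedGraph,
    alphas: np.ndarray,
    orders: tuple[int, ...] = (2, 3, 4, 5),
):
    """Discriminative ratio over a grid of scaling values, per indirect order.

    Returns a tidy table with columns ``alpha``, ``order``, ``r``; singular
    alphas and absent orders yield NaN rows.
    """
    import pandas as pd

    all_orders = edge_orders(g_true)
    present = {k for k in orders if (all_orders == k).any()}
    rows = []
    for a in np.asarray(alphas, dtype=float):
        try:
            A = deconvolve(obs, a)
        except np.linalg.LinAlgError:
            A = None
        for k in orders:
            if A is None or k not in present:
                r = np.nan
            else:
                r = discriminative_ratio(A, obs, g_true, k)
            rows.append({"alpha": a, "order": k, "r": r})
    return pd.DataFrame(rows)
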