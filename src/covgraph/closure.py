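"""Transitive-closure algebra linking concentration and covariance graphs.

A Gaussian model with precision ``Theta = D(I - A)D`` (``D`` diagonal,
``A`` symmetric with zero diagonal) has covariance

    Sigma = D^{-1}(I - A)^{-1}D^{-1} = D^{-1}(I + A*)D^{-1},

where ``A* = sum_{m>=1} A^m = (I - A)^{-1} - I`` is the weighted transitive
closure of the graph with adjacency ``A`` — the (i, j) entry sums, over every
walk from i to j, the product of edge weights along the walk.  The series
converges when the spectral radius of ``A`` is below one.  Marginal
(covariance-graph) edges are therefore direct concentration edges plus the
transitive contributions of all indirect walks.

For trees the correlation matrix obeys a product rule: the correlation of a
non-adjacent pair equals the product of correlations along the unique path
joining them, i.e. the covariance graph is the minimal transitive closure of
the concentration graph re-weighted with correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import linalg

from .graphs import WeightedGraph
from .synthetic import CovarianceModel

__all__ = [
    "ConcentrationModel",
    "ClosureResult",
    "neumann_closure",
    "closure_exact",
    "covariance_from_concentration",
    "star_closure",
    "minimal_transitive_closure",
    "verify_product_rule",
    "mle_completion_3node",
    "spectral_radius",
    "DivergenceError",
]


class DivergenceError(ValueError):
    """Spectral radius at or above one: the closure series diverges."""


@dataclass(frozen=True)
class ConcentrationModel:
    """Precision-side objects: Theta, partial correlations, scaling, structure.

    ``Theta = D(I - A)D`` with ``D_ii = sqrt(Theta_ii)``; off-diagonal
    partial correlations are ``rho_ij = -Theta_ij / sqrt(Theta_ii Theta_jj)
    = A_ij``, so ``rho = I + A``.
    """

    Theta: np.ndarray
    D: np.ndarray
    A: np.ndarray
    rho: np.ndarray

    @classmethod
    def from_precision(cls, Theta: np.ndarray) -> "ConcentrationModel":
        Theta = np.asarray(Theta, dtype=float)
        ev_min = linalg.eigvalsh(Theta, subset_by_index=(0, 0))[0]
        if ev_min <= 0:
            raise ValueError("precision matrix must be positive definite")
        d = np.sqrt(np.diag(Theta))
        A = np.eye(len(Theta)) - Theta / np.outer(d, d)
        np.fill_diagonal(A, 0.0)
        return cls(Theta=Theta, D=np.diag(d), A=A, rho=np.eye(len(Theta)) + A)

    @classmethod
    def from_structure(cls, A: np.ndarray, D: np.ndarray | None = None) -> "ConcentrationModel":
        A = np.asarray(A, dtype=float)
        p = A.shape[0]
        D = np.eye(p) if D is None else np.asarray(D, dtype=float)
        Theta = D @ (np.eye(p) - A) @ D
        return cls(Theta=Theta, D=D, A=A, rho=np.eye(p) + A)

    @property
    def p(self) -> int:
        return self.Theta.shape[0]


@dataclass(frozen=True)
class ClosureResult:
    """Weighted transitive closure ``A*`` (diagonal may be nonzero)."""

    A_star: np.ndarray
    converged: bool
    terms_used: int


def spectral_radius(A: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(A))))


def neumann_closure(
    A: np.ndarray, tol: float = 1e-12, max_terms: int = 10_000
) -> ClosureResult:
    """Transitive closure by the truncated Neumann series ``sum_m A^m``.

    Requires spectral radius strictly below one; terms are accumulated until
    the newest term's max-abs entry drops below ``tol``.
    """
    A = np.asarray(A, dtype=float)
    sr = spectral_radius(A)
    if sr >= 1 - 1e-9:
        raise DivergenceError(f"spectral radius {sr:.6f} >= 1; series diverges")
    total = A.copy()
    term = A.copy()
    m = 1
    converged = False
    while m < max_terms:
        term = term @ A
        total += term
        m += 1
        if np.max(np.abs(term)) < tol:
            converged = True
            break
    return ClosureResult(A_star=total, converged=converged, terms_used=m)


def closure_exact(A: np.ndarray) -> ClosureResult:
    """Exact closure ``A* = A(I - A)^{-1} = (I - A)^{-1} - I`` by direct solve."""
    A = np.asarray(A, dtype=float)
    I = np.eye(A.shape[0])
    try:
        A_star = linalg.solve(I - A, A, assume_a="gen")
    except linalg.LinAlgError as e:
        raise linalg.LinAlgError(f"I - A is singular: {e}") from e
    return ClosureResult(A_star=A_star, converged=True, terms_used=0)


def covariance_from_concentration(model: ConcentrationModel) -> CovarianceModel:
    """Covariance from the closure route ``Sigma = D^{-1}(I + A*)D^{-1}``.

    Equals ``Theta^{-1}``; both routes agree to solver precision.
    """
    ev_min = linalg.eigvalsh(model.Theta, subset_by_index=(0, 0))[0]
    if ev_min <= 0:
        raise ValueError("precision matrix must be positive definite")
    A_star = closure_exact(model.A).A_star
    d = np.diag(model.D)
    Sigma = (np.eye(model.p) + A_star) / np.outer(d, d)
    Sigma = (Sigma + Sigma.T) / 2
    lam = np.sqrt(np.diag(Sigma))
    C = Sigma / np.outer(lam, lam)
    np.fill_diagonal(C, 1.0)
    return CovarianceModel(Sigma=Sigma, C=C, Lambda=np.diag(lam))


def _star_hub(A: np.ndarray) -> int | None:
    """Return the hub index if the nonzero pattern of A is a star, else None."""
    pattern = A != 0
    np.fill_diagonal(pattern, False)
    deg = pattern.sum(axis=0)
    nz = np.nonzero(deg)[0]
    if len(nz) == 0:
        return 0
    hubs = np.nonzero(deg == deg.max())[0]
    k = int(hubs[0])
    # every edge must touch the hub
    rows, cols = np.nonzero(np.triu(pattern, 1))
    if all(k in (r, c) for r, c in zip(rows, cols)):
        return k
    return None


def star_closure(A: np.ndarray, k: int | None = None) -> ClosureResult:
    """Closed-form closure of a star graph centred at hub ``k``.

    With ``c = 1 - sum_l A_kl A_lk``:
    ``A*_ij = A_ik A_kj / c`` for leaves i, j; ``A*_ik = A_ik / c``;
    ``A*_kk = 1/c - 1``.  Leaf diagonals follow from the walk algebra:
    ``A*_ii = A_ik^2 / c``.
    """
    A = np.asarray(A, dtype=float)
    hub = _star_hub(A)
    if hub is None:
        raise ValueError("adjacency is not a star (edges not all incident to one hub)")
    if k is None:
        k = hub
    elif _star_hub(A) != k and np.count_nonzero(A) > 0:
        # permit explicit k if consistent with the pattern
        pattern = A != 0
        np.fill_diagonal(pattern, False)
        rows, cols = np.nonzero(np.triu(pattern, 1))
        if not all(k in (r, c) for r, c in zip(rows, cols)):
            raise ValueError(f"node {k} is not the hub of this star")
    c = 1.0 - float(A[k] @ A[:, k])
    if c <= 0:
        raise DivergenceError(f"star normaliser c = {c:.6f} <= 0; closure diverges")
    a = A[:, k].copy()  # a[k] = 0
    A_star = np.outer(a, a) / c
    A_star[:, k] = a / c
    A_star[k, :] = a / c
    A_star[k, k] = 1.0 / c - 1.0
    return ClosureResult(A_star=A_star, converged=True, terms_used=0)


def minimal_transitive_closure(g: WeightedGraph, node_limit: int = 500) -> WeightedGraph:
    """Minimal transitive closure: weights summed over minimal-length paths.

    Output has an edge (i, j) iff a path joins them in ``g``; its weight is
    the sum over all shortest (minimal-length) simple paths of the product of
    edge weights along the path.  For trees this is the unique-path product.
    """
    if g.p > node_limit:
        raise ValueError(
            f"graph has {g.p} nodes; exceeds enumeration limit {node_limit}"
        )
    G = nx.Graph()
    G.add_nodes_from(range(g.p))
    for i, j, w in g.edges():
        G.add_edge(i, j)
    out = np.zeros((g.p, g.p))
    adj = g.adjacency
    for comp in nx.connected_components(G):
        nodes = sorted(comp)
        for ai, i in enumerate(nodes):
            for j in nodes[ai + 1 :]:
                total = 0.0
                for path in nx.all_shortest_paths(G, i, j):
                    prod = 1.0
                    for u, v in zip(path[:-1], path[1:]):
                        prod *= adj[u, v]
                    total += prod
                out[i, j] = out[j, i] = total
    return WeightedGraph(out)


def verify_product_rule(model: CovarianceModel, g: WeightedGraph) -> dict:
    """Check the tree product rule on a correlation matrix.

    For every non-adjacent pair (i, j) in the tree ``g``, the correlation
    ``C_ij`` must equal the product of the correlations along the unique path
    joining i and j.  Returns a report with the max-abs residual.
    """
    G = g.to_networkx()
    if not nx.is_forest(G):
        raise ValueError("product rule applies to trees/forests only")
    C = model.C
    residuals = []
    for comp in nx.connected_components(G):
        nodes = sorted(comp)
        for ai, i in enumerate(nodes):
            for j in nodes[ai + 1 :]:
                if g.adjacency[i, j] != 0:
                    continue
                path = nx.shortest_path(G, i, j)
                prod = 1.0
                for u, v in zip(path[:-1], path[1:]):
                    prod *= C[u, v]
                residuals.append(abs(C[i, j] - prod))
    max_resid = max(residuals) if residuals else 0.0
    return {"max_residual": float(max_resid), "n_pairs": len(residuals)}


def mle_completion_3node(S: np.ndarray) -> CovarianceModel:
    """Maximum-likelihood covariance completion for the 3-node chain 1-2-3.

    Under the constraint ``Theta_13 = 0`` (nodes 1 and 3 conditionally
    independent given node 2) the MLE keeps every entry of ``S`` except the
    (1,3) entry, which computes to ``s12 * s23 / s22``.  The resulting
    precision has an exact zero at (1,3).
    """
    S = np.asarray(S, dtype=float)
    if S.shape != (3, 3):
        raise ValueError("completion formula applies to p = 3 only")
    if S[1, 1] == 0:
        raise ValueError("s22 = 0: completion undefined")
    if abs(np.linalg.det(S)) < 1e-14:
        raise ValueError("S is singular; MLE not unique")
    Sigma = S.copy()
    Sigma[0, 2] = Sigma[2, 0] = S[0, 1] * S[1, 2] / S[1, 1]
    lam = np.sqrt(np.diag(Sigma))
    C = Sigma / np.outer(lam, lam)
    np.fill_diagonal(C, 1.0)
    return CovarianceModel(Sigma=Sigma, C=C, Lambda=np.diag(lam))
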