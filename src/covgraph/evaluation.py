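"""Evaluation of reconstructed graphs against a known truth.

Edges are unordered node pairs; the diagonal is never counted.  Besides the
usual confusion counts and ROC rates, two study-specific quantities are
used throughout the benchmarks:

* the Euclidean distance from a prediction to the truth in the (correctly
  predicted, total predicted) plane,

      d_E = sqrt((T_R - C_pred)^2 + (T_R - T_pred)^2),

  which is zero iff the prediction recovers exactly the true edge set;
* the *sensitivity* — correctly predicted over total predicted edges.
  Note this is a precision-type ratio over the prediction, not the true
  positive rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graphs import WeightedGraph
from .synthetic import CovarianceModel

__all__ = [
    "EvaluationRecord",
    "confusion",
    "distance_to_truth",
    "roc_curve",
    "optimal_parameter",
    "random_guess_record",
    "edge_weight_separability",
]


@dataclass(frozen=True)
class EvaluationRecord:
    """Confusion counts and derived rates for one predicted graph."""

    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def T_R(self) -> int:
        """True edge count."""
        return self.TP + self.FN

    @property
    def T_pred(self) -> int:
        """Total predicted edges."""
        return self.TP + self.FP

    @property
    def C_pred(self) -> int:
        """Correctly predicted edges (= TP)."""
        return self.TP

    @property
    def d_E(self) -> float:
        return float(np.hypot(self.T_R - self.C_pred, self.T_R - self.T_pred))

    @property
    def TPR(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN else np.nan

    @property
    def FPR(self) -> float:
        return self.FP / (self.FP + self.TN) if self.FP + self.TN else np.nan

    @property
    def sensitivity(self) -> float:
        """Correct over total predicted; NaN when nothing is predicted."""
        return self.TP / self.T_pred if self.T_pred else np.nan


def _edge_masks(pred: WeightedGraph, truth: WeightedGraph) -> tuple[np.ndarray, np.ndarray]:
    if pred.p != truth.p:
        raise ValueError("graphs must have the same node count")
    return pred.edge_mask, truth.edge_mask


def confusion(pred: WeightedGraph, truth: WeightedGraph) -> EvaluationRecord:
    """Confusion counts of a predicted edge set over unordered pairs."""
    pm, tm = _edge_masks(pred, truth)
    return confusion_from_masks(pm, tm)


def confusion_from_masks(pred_mask: np.ndarray, true_mask: np.ndarray) -> EvaluationRecord:
    TP = int(np.sum(pred_mask & true_mask))
    FP = int(np.sum(pred_mask & ~true_mask))
    FN = int(np.sum(~pred_mask & true_mask))
    TN = int(np.sum(~pred_mask & ~true_mask))
    return EvaluationRecord(TP=TP, FP=FP, FN=FN, TN=TN)


def distance_to_truth(record: EvaluationRecord) -> float:
    return record.d_E


def roc_curve(
    scores: np.ndarray, truth: WeightedGraph, grid: np.ndarray | None = None
) -> list[tuple[float, float]]:
    """(FPR, TPR) pairs from thresholding ``|scores|`` over a cutoff grid.

    The returned curve is sorted by descending cutoff, so both coordinates
    are non-decreasing along it; the endpoints (0,0) and (1,1) correspond to
    cutoffs above the max and below the min score.
    """
    scores = np.asarray(scores, dtype=float)
    iu = np.triu_indices(truth.p, 1)
    s = np.abs(scores[iu])
    tm = truth.edge_mask
    if grid is None:
        grid = np.unique(s)
    grid = np.sort(np.asarray(grid, dtype=float))[::-1]
    pts = [(0.0, 0.0)]
    for cut in grid:
        rec = confusion_from_masks(s > cut, tm)
        pts.append((rec.FPR, rec.TPR))
    rec = confusion_from_masks(s >= grid[-1] if len(grid) else s > -np.inf, tm)
    pts.append((1.0, 1.0))
    return pts


def optimal_parameter(
    records: list, truth: WeightedGraph
) -> tuple[float, EvaluationRecord]:
    """Pick the tuning value minimising d_E; ties resolve to the sparser fit.

    ``records`` is a list of :class:`~covgraph.estimators.EstimateRecord`
    across a parameter grid.  "Sparser" means the larger penalty/threshold.
    """
    if not records:
        raise ValueError("empty grid of estimates")
    best = None
    for rec in records:
        ev = confusion(rec.graph, truth)
        key = (ev.d_E, -rec.param)
        if best is None or key < best[0]:
            best = (key, rec.param, ev)
    return best[1], best[2]


def random_guess_record(
    t_pred: int, truth: WeightedGraph, rng: np.random.Generator
) -> EvaluationRecord:
    """Baseline: predict ``t_pred`` edges uniformly at random.

    Matched in size to a method's output, as a quality-control floor; the
    expected TP is hypergeometric: ``t_pred * T_R / (p(p-1)/2)``.
    """
    n_pairs = truth.p * (truth.p - 1) // 2
    t_pred = min(t_pred, n_pairs)
    pick = rng.choice(n_pairs, size=t_pred, replace=False)
    mask = np.zeros(n_pairs, dtype=bool)
    mask[pick] = True
    return confusion_from_masks(mask, truth.edge_mask)


def edge_weight_separability(model: CovarianceModel, truth: WeightedGraph) -> dict:
    """Direct vs indirect |correlation| distributions and the best threshold.

    Splits the off-diagonal correlation magnitudes into direct edges (pairs
    in the concentration graph) and indirect edges (the remaining covariance-
    graph pairs).  Reports both samples, their overlap fraction and the
    threshold minimising total misclassification (direct below + indirect
    above); when the two classes are separable the threshold lies strictly
    between them and misclassification is zero.
    """
    iu = np.triu_indices(truth.p, 1)
    w = np.abs(model.C[iu])
    tm = truth.edge_mask
    direct = w[tm]
    indirect = w[~tm]
    if len(indirect) == 0:
        return {
            "direct": direct, "indirect": indirect, "threshold": np.nan,
            "misclassified": 0, "overlap": 0.0, "degenerate": True,
        }
    vals = np.unique(np.concatenate([[0.0], w]))
    # candidate cuts sit strictly between observed magnitudes
    mids = (vals[:-1] + vals[1:]) / 2 if len(vals) > 1 else vals
    mids = np.concatenate([mids, [vals[-1] * 1.05 + 1e-12]])
    best_cut, best_err = 0.0, np.inf
    for c in mids:
        err = int(np.sum(direct <= c) + np.sum(indirect > c))
        if err < best_err:
            best_cut, best_err = float(c), err
    overlap = 0.0
    if len(direct):
        lo, hi = indirect.max(), direct.min()
        overlap = float(np.mean((direct <= lo)) if hi <= lo else 0.0)
    return {
        "direct": direct,
        "indirect": indirect,
        "threshold": best_cut,
        "misclassified": int(best_err),
        "overlap": overlap,
        "degenerate": False,
    }
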