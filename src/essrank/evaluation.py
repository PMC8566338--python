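"""Ranking-quality metrics for essential-protein prediction.

Top-k% precision, jackknife cumulative curves, ROC/PR with AUC
(scikit-learn under the hood), and pairwise method-overlap statistics.
Top-k cutoffs use ceil(p/100 * N); gold-standard proteins outside the
ranked universe are dropped with a warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_auc_score, roc_curve

logger = logging.getLogger(__name__)

__all__ = [
    "topk_precision",
    "jackknife_curve",
    "roc_pr",
    "overlap_diff",
    "topk_cutoff",
    "EvalReport",
    "evaluate_ranking",
]

DEFAULT_PERCENTS = (1, 5, 10, 15, 20, 25)


def topk_cutoff(percent: float, n: int) -> int:
    """Cutoff for a top-k% slice: ceil(percent/100 * N)."""
    return math.ceil(percent / 100.0 * n)


def _restrict_gold(ranking: Sequence[str], essential: set[str]) -> set[str]:
    universe = set(ranking)
    gold = essential & universe
    if len(gold) < len(essential):
        logger.warning(
            "%d gold-standard proteins are outside the ranked universe and "
            "were dropped", len(essential) - len(gold),
        )
    return gold


def topk_precision(
    ranking: Sequence[str],
    essential: set[str],
    percents: Sequence[float] = DEFAULT_PERCENTS,
) -> dict[float, dict[str, float]]:
    """Precision (in %) among the top ceil(p% * N) ranked proteins, per p."""
    if not ranking:
        raise ValueError("empty ranking")
    gold = _restrict_gold(ranking, essential)
    out: dict[float, dict[str, float]] = {}
    for p in percents:
        cutoff = topk_cutoff(p, len(ranking))
        hits = sum(1 for prot in ranking[:cutoff] if prot in gold)
        out[p] = {
            "cutoff": cutoff,
            "hits": hits,
            "precision": 100.0 * hits / cutoff if cutoff else 0.0,
        }
    return out


def jackknife_curve(
    ranking: Sequence[str], essential: set[str], depth: int = 1000
) -> np.ndarray:
    """Cumulative count of true essentials among the top r proteins,
    r = 1..min(depth, N)."""
    gold = _restrict_gold(ranking, essential)
    depth = min(depth, len(ranking))
    hits = np.fromiter((p in gold for p in ranking[:depth]), dtype=int, count=depth)
    return np.cumsum(hits)


def roc_pr(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points, PR points, and AUC for a score vector and binary labels.

    AUC is the Mann–Whitney probability (ties rank-averaged). Raises on
    one-class input.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present to compute ROC/PR")
    fpr, tpr, _ = roc_curve(labels, scores)
    prec, rec, _ = precision_recall_curve(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    return np.column_stack([fpr, tpr]), np.column_stack([rec, prec]), auc


def overlap_diff(
    rank_a: set[str], rank_b: set[str], essential: set[str]
) -> dict[str, float]:
    """Overlap statistics between two methods' top-k sets.

    Returns the intersection size, the two difference-set sizes, and the
    percentage of essential proteins inside each difference set.
    """
    a_only = rank_a - rank_b
    b_only = rank_b - rank_a
    def pct(s: set[str]) -> float:
        return 100.0 * len(s & essential) / len(s) if s else 0.0
    return {
        "intersection": len(rank_a & rank_b),
        "a_minus_b": len(a_only),
        "b_minus_a": len(b_only),
        "essential_pct_a_minus_b": pct(a_only),
        "essential_pct_b_minus_a": pct(b_only),
    }


@dataclass
class EvalReport:
    """Bundle of all evaluation blocks, serializable to JSON."""

    topk: dict[float, dict[str, float]]
    jackknife: list[int]
    auc: float | None
    roc: list[list[float]] = field(default_factory=list)
    pr: list[list[float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "topk_precision": {str(k): v for k, v in self.topk.items()},
            "jackknife": list(map(int, self.jackknife)),
            "auc": self.auc,
            "roc": self.roc,
            "pr": self.pr,
        }


def evaluate_ranking(
    ranking: Sequence[str],
    scores_by_id: dict[str, float],
    essential: set[str],
    percents: Sequence[float] = DEFAULT_PERCENTS,
    jackknife_depth: int = 1000,
    include_curves: bool = False,
) -> EvalReport:
    """Full metric bundle for one ranking against a gold standard."""
    topk = topk_precision(ranking, essential, percents)
    jack = jackknife_curve(ranking, essential, jackknife_depth)
    gold = _restrict_gold(ranking, essential)
    labels = np.array([1 if p in gold else 0 for p in ranking])
    scores = np.array([scores_by_id[p] for p in ranking])
    auc = None
    roc_pts: list[list[float]] = []
    pr_pts: list[list[float]] = []
    if 0 < labels.sum() < len(labels):
        roc_arr, pr_arr, auc = roc_pr(scores, labels)
        if include_curves:
            roc_pts = roc_arr.tolist()
            pr_pts = pr_arr.tolist()
    return EvalReport(topk, jack.tolist(), auc, roc_pts, pr_pts)
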