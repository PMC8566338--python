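"""Damped iterative score propagation over the distribution-rate matrix.

The distribution-rate matrix spreads a protein's score to its PPI neighbors
in proportion to edge weight times the neighbor's initial score:

    D(k, r) = WP(k, r) * s0(r) / sum_{i in NG(k)} s0(i)   (0 off the edge set)

rows are then normalized to sum 1 by default so the damped iteration

    s(t+1) = alpha * s(t) @ D + (1 - alpha) * s(0)

is a contraction with factor at most alpha and converges geometrically.
Rows whose neighbor scores sum to zero (or isolated proteins) stay all-zero;
the restart term replenishes the leaked mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import PPINetwork, ProteinRegistry, ranking_order

__all__ = ["build_drpm", "iterate", "rank", "IterationResult"]


def build_drpm(
    wp: np.ndarray,
    proscore: np.ndarray,
    ppi: PPINetwork | None = None,
    normalize_rows: bool = True,
) -> np.ndarray:
    """Build the distribution-rate matrix from edge weights and initial scores.

    ``wp`` must already be masked to the PPI edge set; passing ``ppi``
    re-asserts the mask. With ``normalize_rows`` (default) every nonzero row
    is scaled to sum 1.
    """
    wp = np.asarray(wp, dtype=float)
    s0 = np.asarray(proscore, dtype=float)
    if (s0 < 0).any():
        raise ValueError("initial scores must be nonnegative")
    if ppi is not None:
        wp = np.where(ppi.adjacency(), wp, 0.0)
    support = wp != 0
    # denominator: sum of initial scores over each row's neighbors
    denom = (support * s0[None, :]).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(
            support & (denom[:, None] > 0),
            wp * s0[None, :] / denom[:, None],
            0.0,
        )
    if normalize_rows:
        rowsum = d.sum(axis=1)
        nz = rowsum > 0
        d[nz] = d[nz] / rowsum[nz, None]
    return d


@dataclass
class IterationResult:
    """Final propagation state: scores, convergence flag, and the history of
    L2 step norms."""

    scores: np.ndarray
    n_iter: int
    converged: bool
    history: list[float]
    residual: float


def iterate(
    drpm: np.ndarray,
    proscore0: np.ndarray,
    alpha: float = 0.9,
    eps: float = 1e-6,
    max_iter: int = 100,
) -> IterationResult:
    """Run s <- alpha * s @ D + (1 - alpha) * s0 until the L2 step norm
    drops below ``eps`` or ``max_iter`` is reached."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if eps <= 0:
        raise ValueError("eps must be positive")
    d = np.asarray(drpm, dtype=float)
    s0 = np.asarray(proscore0, dtype=float)
    s = s0.copy()
    history: list[float] = []
    converged = False
    t = 0
    for t in range(1, max_iter + 1):
        s_new = alpha * (s @ d) + (1.0 - alpha) * s0
        if not np.isfinite(s_new).all():
            raise FloatingPointError(f"non-finite scores at iteration {t}")
        step = float(np.linalg.norm(s_new - s))
        history.append(step)
        s = s_new
        if step < eps:
            converged = True
            break
    residual = float(np.linalg.norm(s - alpha * (s @ d) - (1.0 - alpha) * s0))
    return IterationResult(s, t, converged, history, residual)


def rank(
    scores: np.ndarray,
    registry: ProteinRegistry,
    initial: np.ndarray | None = None,
) -> list[str]:
    """Protein IDs in descending score order with deterministic tie-breaks
    (descending initial score, then ascending ID)."""
    return [registry[k] for k in ranking_order(scores, registry, initial)]
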