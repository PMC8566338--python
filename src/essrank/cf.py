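"""Two-sided collaborative filtering on the protein–domain bipartite network.

The protein–domain adjacency is sparse because domain annotation is
incomplete. Densification treats it as a recommender problem, run
symmetrically from both sides of the bipartite graph:

* protein-based pass — proteins sharing domains are similar (cosine of
  binary annotation profiles); the similarity-weighted adjacency product
  scores every (protein, domain) cell, and cells scoring strictly above the
  column-mean standard become new edges;
* domain-based pass — the same with the roles of proteins and domains
  swapped, starting from the transposed adjacency.

Both passes start from the ORIGINAL adjacency (they are independent, not
chained) and merge by union into the mutual recommendation matrix, which
only ever adds edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import BipartiteNet

__all__ = [
    "cooccurrence",
    "similarity",
    "recommend_matrix",
    "recommendation_standard",
    "apply_recommendations",
    "mutual_recommend",
    "run_cf",
    "CFResult",
]


def _as_binary(adjacency: np.ndarray) -> np.ndarray:
    a = np.asarray(adjacency)
    if a.ndim != 2 or not np.isin(a, (0, 1)).all():
        raise ValueError("adjacency must be a binary 2-D matrix")
    return a.astype(float)


def cooccurrence(adjacency: np.ndarray) -> np.ndarray:
    """0/1 co-occurrence matrix over the rows of a binary adjacency.

    Entry (i, j) is 1 iff rows i and j share at least one neighbor on the
    other side; the diagonal is zero.
    """
    a = _as_binary(adjacency)
    shared = a @ a.T
    cm = (shared > 0).astype(np.uint8)
    np.fill_diagonal(cm, 0)
    return cm


def similarity(adjacency: np.ndarray) -> np.ndarray:
    """Cosine similarity of binary rows: |N(i) ∩ N(j)| / sqrt(|N(i)|·|N(j)|).

    The diagonal is zero and rows with no neighbors get similarity 0 to
    everything (the 0/0 case is resolved to the limit value).
    """
    a = _as_binary(adjacency)
    shared = a @ a.T
    deg = a.sum(axis=1)
    denom = np.sqrt(np.outer(deg, deg))
    with np.errstate(divide="ignore", invalid="ignore"):
        sm = np.where(denom > 0, shared / denom, 0.0)
    np.fill_diagonal(sm, 0.0)
    return sm


def recommend_matrix(sim: np.ndarray, adjacency: np.ndarray) -> np.ndarray:
    """Recommendation matrix: the product of a similarity matrix and the
    adjacency it was derived from (similarity-weighted vote of annotated
    rows for each column)."""
    sim = np.asarray(sim, dtype=float)
    adjacency = np.asarray(adjacency, dtype=float)
    if sim.shape[1] != adjacency.shape[0]:
        raise ValueError(
            f"shape mismatch: similarity {sim.shape} x adjacency {adjacency.shape}"
        )
    return sim @ adjacency


def recommendation_standard(rm: np.ndarray) -> np.ndarray:
    """Per-column recommendation standard: the column mean over all rows
    (zeros included)."""
    rm = np.asarray(rm, dtype=float)
    return rm.mean(axis=0)


def apply_recommendations(
    rm: np.ndarray, std: np.ndarray, adjacency: np.ndarray
) -> np.ndarray:
    """Add an edge at every zero cell whose recommendation score strictly
    exceeds its column standard; existing edges are never removed."""
    adjacency = np.asarray(adjacency)
    added = (np.asarray(rm) > np.asarray(std)[None, :]) & (adjacency == 0)
    return np.where(added, 1, adjacency).astype(np.uint8)


def mutual_recommend(uam_pd: np.ndarray, uam_dp: np.ndarray) -> np.ndarray:
    """Merge the protein-side (N x M) and domain-side (M x N) updated
    adjacencies into the binary mutual recommendation matrix.

    The sum-capped-at-one combination of two binary matrices is their
    element-wise logical OR.
    """
    uam_pd = np.asarray(uam_pd)
    uam_dp = np.asarray(uam_dp)
    if uam_pd.shape != uam_dp.T.shape:
        raise ValueError(
            f"shape mismatch: {uam_pd.shape} vs transposed {uam_dp.shape}"
        )
    return ((uam_pd == 1) | (uam_dp.T == 1)).astype(np.uint8)


@dataclass
class CFResult:
    """Output of the two-sided collaborative-filtering densification.

    ``added_protein_side`` / ``added_domain_side`` record provenance of
    every edge the respective pass added, as (protein_index, domain_index).
    """

    mrm: np.ndarray
    added_protein_side: set[tuple[int, int]] = field(default_factory=set)
    added_domain_side: set[tuple[int, int]] = field(default_factory=set)

    @property
    def n_added(self) -> int:
        return len(self.added_protein_side | self.added_domain_side)


def run_cf(pdi: BipartiteNet, iterations: int = 1) -> CFResult:
    """Run both collaborative-filtering passes once (default) and merge.

    With ``iterations > 1`` the whole two-sided step is repeated on the
    merged output; the default single pass is the standard procedure.
    """
    am_pd = pdi.adjacency.astype(np.uint8)
    added_p: set[tuple[int, int]] = set()
    added_d: set[tuple[int, int]] = set()
    for _ in range(iterations):
        am_dp = am_pd.T
        # protein-based pass
        sm_pp = similarity(am_pd)
        rm_pd = recommend_matrix(sm_pp, am_pd)
        uam_pd = apply_recommendations(rm_pd, recommendation_standard(rm_pd), am_pd)
        # domain-based pass, independently from the original adjacency
        sm_dd = similarity(am_dp)
        rm_dp = recommend_matrix(sm_dd, am_dp)
        uam_dp = apply_recommendations(rm_dp, recommendation_standard(rm_dp), am_dp)
        mrm = mutual_recommend(uam_pd, uam_dp)
        added_p |= {tuple(x) for x in np.argwhere((uam_pd == 1) & (am_pd == 0))}
        added_d |= {
            (int(j), int(i))
            for i, j in np.argwhere((uam_dp == 1) & (am_dp == 0))
        }
        am_pd = mrm
    return CFResult(mrm=am_pd, added_protein_side=added_p, added_domain_side=added_d)
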