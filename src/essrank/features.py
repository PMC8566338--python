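"""Per-protein feature scores and their entropy-weighted fusion.

Three biological features — subcellular-localization weight (ProSub),
max-normalized ortholog count (ProOrt), summed neighbor co-expression
(ProExp) — are min–max scaled, fused with entropy weights into proBio, and
blended with the max-normalized triangle topology score (ProTri):

    proscore(k) = lambda * proBio(k) + (1 - lambda) * ProTri(k)

The entropy-weight scheme gives a feature more weight the more unevenly it
is distributed across proteins (lower Shannon entropy of its column
proportions); a constant feature carries no information and gets weight 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AnnotationTable, PPINetwork

__all__ = [
    "LocationScores",
    "FeatureTable",
    "location_scores",
    "prosub",
    "proort",
    "pcc",
    "proexp",
    "protri",
    "entropy_weights",
    "fuse",
    "initial_score",
    "compute_features",
]


@dataclass
class LocationScores:
    """Per-compartment weights derived from how populated each compartment is.

    ``eve[i] = count[i] / mean(count)``: compartments housing more proteins
    score higher, so a protein accumulates score for residing in populous
    compartments (where essential proteins concentrate).
    """

    compartments: list[str]
    counts: np.ndarray
    average: float
    eve: np.ndarray


def location_scores(
    annotations: AnnotationTable,
    vocabulary: list[str],
    protein_ids: list[str] | None = None,
) -> LocationScores:
    """Count proteins per compartment and weight each compartment by its
    count over the average count."""
    if not vocabulary:
        raise ValueError("compartment vocabulary must be nonempty")
    universe = protein_ids if protein_ids is not None else list(annotations.subcellular)
    counts = np.zeros(len(vocabulary))
    pos = {c: i for i, c in enumerate(vocabulary)}
    for p in universe:
        for comp in annotations.subcellular.get(p, ()):
            if comp in pos:
                counts[pos[comp]] += 1
    avg = counts.sum() / len(vocabulary)
    eve = counts / avg if avg > 0 else np.zeros_like(counts)
    return LocationScores(list(vocabulary), counts, float(avg), eve)


def prosub(protein_id: str, loc: LocationScores, annotations: AnnotationTable) -> float:
    """Subcellular score: sum of compartment weights over the protein's
    compartments (0 if unannotated)."""
    pos = {c: i for i, c in enumerate(loc.compartments)}
    return float(
        sum(loc.eve[pos[c]] for c in annotations.subcellular.get(protein_id, ()) if c in pos)
    )


def proort(counts: np.ndarray) -> np.ndarray:
    """Ortholog counts divided by the maximum count over the network
    (all zero when the maximum is zero)."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("ortholog counts must be nonnegative")
    mx = counts.max() if counts.size else 0.0
    return counts / mx if mx > 0 else np.zeros_like(counts)


def pcc(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation; 0 when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        return 0.0
    return float(((x - x.mean()) * (y - y.mean())).sum() / ((x.size - 1) * sx * sy))


def proexp(ppi: PPINetwork, annotations: AnnotationTable) -> np.ndarray:
    """Co-expression score: sum of Pearson correlation to PPI neighbors,
    floored at 0, then max-normalized.

    Proteins without an expression vector contribute (and receive)
    correlation 0.
    """
    n = ppi.n
    expr = [annotations.expression.get(ppi.registry[k]) for k in range(n)]
    ng = ppi.neighbors()
    raw = np.zeros(n)
    cache: dict[tuple[int, int], float] = {}
    for k in range(n):
        if expr[k] is None:
            continue
        total = 0.0
        for r in ng[k]:
            if expr[r] is None:
                continue
            key = (k, r) if k < r else (r, k)
            if key not in cache:
                cache[key] = pcc(expr[key[0]], expr[key[1]])
            total += cache[key]
        raw[k] = total
    np.maximum(raw, 0.0, out=raw)  # negative co-expression is no evidence
    mx = raw.max()
    return raw / mx if mx > 0 else raw


def protri(ppi: PPINetwork, normalize: bool = True) -> np.ndarray:
    """Triangle topology score: sum over neighbors of shared-neighbor
    counts, divided by the protein's degree; optionally max-normalized.

    The raw value equals twice the number of triangles through the protein
    divided by its degree; isolated proteins score 0.
    """
    ng = ppi.neighbors()
    raw = np.zeros(ppi.n)
    for k in range(ppi.n):
        if not ng[k]:
            continue
        raw[k] = sum(len(ng[k] & ng[r]) for r in ng[k]) / len(ng[k])
    if normalize:
        mx = raw.max()
        if mx > 0:
            raw = raw / mx
    return raw


def _minmax(col: np.ndarray) -> np.ndarray:
    lo, hi = col.min(), col.max()
    if hi == lo:
        return col.copy()  # constant column: keep as-is (uniform proportions)
    return (col - lo) / (hi - lo)


def entropy_weights(bf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shannon entropy per feature column and the resulting weights.

    Columns are converted to proportions (0/0 -> 0); entropy uses the
    0*ln(0) := 0 convention and is normalized by ln(N). Weights are
    (1 - e_j) renormalized; when every column attains maximal entropy the
    weights fall back to uniform.
    """
    bf = np.asarray(bf, dtype=float)
    if (bf < 0).any():
        raise ValueError("feature matrix must be nonnegative")
    n, m = bf.shape
    if n < 2:
        raise ValueError("need at least 2 proteins for entropy weighting")
    colsum = bf.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(colsum > 0, bf / colsum, 0.0)
        plogp = np.where(q > 0, q * np.log(q), 0.0)
    e = -plogp.sum(axis=0) / np.log(n)
    # rounding can push e a hair past 1; a maximal-entropy column weighs 0
    one_minus = np.maximum(1.0 - e, 0.0)
    total = one_minus.sum()
    if total <= 0 or np.allclose(e, 1.0):
        w = np.full(m, 1.0 / m)
    else:
        w = one_minus / total
    return e, w


def fuse(bf: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted row sums of the feature matrix (the fused proBio score)."""
    bf = np.asarray(bf, dtype=float)
    w = np.asarray(w, dtype=float)
    if bf.shape[1] != w.shape[0]:
        raise ValueError(f"shape mismatch: bf {bf.shape} vs w {w.shape}")
    return bf @ w


def initial_score(
    probio: np.ndarray, protri_norm: np.ndarray, lam: float = 0.65
) -> np.ndarray:
    """Convex blend of fused biology and topology, rescaled to sum 1 so it
    can serve directly as the restart distribution of the propagation."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    s = lam * np.asarray(probio, float) + (1.0 - lam) * np.asarray(protri_norm, float)
    total = s.sum()
    if total <= 0:
        return np.full_like(s, 1.0 / s.size)
    return s / total


@dataclass
class FeatureTable:
    """All per-protein feature columns plus the fusion products."""

    protein_ids: list[str]
    pro_sub: np.ndarray
    pro_ort: np.ndarray
    pro_exp: np.ndarray
    pro_tri: np.ndarray
    bf: np.ndarray          # min-max scaled (ProSub, ProOrt, ProExp)
    entropy: np.ndarray
    weights: np.ndarray
    pro_bio: np.ndarray
    lam: float
    proscore: np.ndarray    # sum-normalized restart distribution


def compute_features(
    ppi: PPINetwork,
    annotations: AnnotationTable,
    lam: float = 0.65,
    vocabulary: list[str] | None = None,
) -> FeatureTable:
    """Compute, normalize and fuse all feature scores for a PPI network."""
    ids = ppi.registry.ids
    vocab = vocabulary or annotations.compartments
    if vocab:
        loc = location_scores(annotations, vocab, ids)
        sub = np.array([prosub(p, loc, annotations) for p in ids])
    else:
        sub = np.zeros(len(ids))
    ort = proort(np.array([annotations.orthologs.get(p, 0) for p in ids], float))
    exp_ = proexp(ppi, annotations)
    tri = protri(ppi, normalize=True)
    bf = np.column_stack([_minmax(sub), _minmax(ort), _minmax(exp_)])
    e, w = entropy_weights(bf)
    bio = fuse(bf, w)
    score = initial_score(bio, tri, lam)
    return FeatureTable(ids, sub, ort, exp_, tri, bf, e, w, bio, lam, score)
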