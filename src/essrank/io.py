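"""Input/output: registries, network containers, and the flat-file formats.

All tabular inputs are delimited text (tab by default). Lines starting with
``#`` are skipped everywhere. The protein universe is defined by the PPI
edge list; protein–domain and annotation rows referring to proteins outside
that universe are dropped with a warning (or rejected in strict mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Registry",
    "ProteinRegistry",
    "DomainRegistry",
    "PPINetwork",
    "BipartiteNet",
    "AnnotationTable",
    "read_ppi",
    "read_pdi",
    "read_annotations",
    "read_essential",
    "write_ranking",
    "write_pdi",
]


class Registry:
    """Ordered, indexed collection of unique string identifiers.

    Index assignment follows first-appearance order, so reading the same
    file twice yields identical registries.
    """

    def __init__(self, ids: Iterable[str] = ()):  # noqa: D107
        self._ids: list[str] = []
        self._index: dict[str, int] = {}
        for i in ids:
            self.add(i)

    def add(self, identifier: str) -> int:
        """Add *identifier* if new; return its index."""
        idx = self._index.get(identifier)
        if idx is None:
            idx = len(self._ids)
            self._index[identifier] = idx
            self._ids.append(identifier)
        return idx

    def index(self, identifier: str) -> int:
        return self._index[identifier]

    def __contains__(self, identifier: str) -> bool:
        return identifier in self._index

    def __len__(self) -> int:
        return len(self._ids)

    def __getitem__(self, idx: int) -> str:
        return self._ids[idx]

    def __iter__(self):
        return iter(self._ids)

    @property
    def ids(self) -> list[str]:
        return list(self._ids)

    def __eq__(self, other) -> bool:
        return isinstance(other, Registry) and self._ids == other._ids

    def __repr__(self) -> str:  # pragma: no cover
        return f"{type(self).__name__}(n={len(self)})"


class ProteinRegistry(Registry):
    """Registry of protein identifiers; its size is N."""


class DomainRegistry(Registry):
    """Registry of domain accessions; its size is M."""


@dataclass
class PPINetwork:
    """Undirected protein–protein interaction network.

    Self-loops and duplicate edges are never stored; ``edges`` holds each
    undirected pair once as ``(i, j)`` with ``i < j``.
    """

    registry: ProteinRegistry
    edges: set[tuple[int, int]] = field(default_factory=set)

    def add_edge(self, i: int, j: int) -> bool:
        """Add the undirected edge (i, j); ignore self-loops. Return True if new."""
        if i == j:
            return False
        key = (i, j) if i < j else (j, i)
        if key in self.edges:
            return False
        self.edges.add(key)
        return True

    @property
    def n(self) -> int:
        return len(self.registry)

    def neighbors(self) -> list[set[int]]:
        """Neighbor sets NG(p_k) for every protein index."""
        ng: list[set[int]] = [set() for _ in range(self.n)]
        for i, j in self.edges:
            ng[i].add(j)
            ng[j].add(i)
        return ng

    def adjacency(self) -> np.ndarray:
        """Dense boolean adjacency matrix."""
        a = np.zeros((self.n, self.n), dtype=bool)
        for i, j in self.edges:
            a[i, j] = a[j, i] = True
        return a

    def has_edge(self, i: int, j: int) -> bool:
        key = (i, j) if i < j else (j, i)
        return key in self.edges


@dataclass
class BipartiteNet:
    """Binary protein x domain adjacency (the PDI network).

    Only the protein-by-domain orientation is stored; the domain-by-protein
    matrix is its transpose by definition.
    """

    proteins: ProteinRegistry
    domains: DomainRegistry
    adjacency: np.ndarray  # (N, M) uint8, entries in {0, 1}

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.shape != (len(self.proteins), len(self.domains)):
            raise ValueError(
                f"adjacency shape {a.shape} does not match registries "
                f"({len(self.proteins)}, {len(self.domains)})"
            )
        if not np.isin(a, (0, 1)).all():
            raise ValueError("bipartite adjacency must be binary")
        self.adjacency = a.astype(np.uint8)

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_domains(self) -> int:
        return len(self.domains)


@dataclass
class AnnotationTable:
    """Per-protein biological annotations keyed by protein ID.

    Proteins absent from a source simply have no entry; downstream scoring
    treats them as empty set / zero count / missing vector.
    """

    subcellular: dict[str, set[str]] = field(default_factory=dict)
    orthologs: dict[str, int] = field(default_factory=dict)
    expression: dict[str, np.ndarray] = field(default_factory=dict)
    compartments: list[str] = field(default_factory=list)
    n_samples: int = 0


def _parse_rows(path: str | Path, n_cols: int, delimiter: str = "\t"):
    """Yield (line_number, columns) for each non-comment, non-blank line."""
    path = Path(path)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split(delimiter) if delimiter != " " else line.split()
            # tolerate any whitespace when the tab split fails to produce columns
            if len(cols) == 1 and delimiter == "\t":
                cols = line.split()
            if n_cols and len(cols) != n_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_cols} columns, got {len(cols)}"
                )
            yield lineno, cols


def read_ppi(path: str | Path, delimiter: str = "\t") -> PPINetwork:
    """Read a two-column edge list into an undirected PPI network.

    Self-interactions are removed and repeated interactions (in either
    order) collapse to a single undirected edge; proteins appearing only in
    dropped self-loops are retained as isolated nodes.
    """
    registry = ProteinRegistry()
    net = PPINetwork(registry)
    seen_any = False
    for _, (a, b) in _parse_rows(path, 2, delimiter):
        seen_any = True
        ia, ib = registry.add(a), registry.add(b)
        net.add_edge(ia, ib)
    if not seen_any:
        raise ValueError(f"{path}: empty PPI file")
    return net


def read_pdi(
    path: str | Path,
    registry: ProteinRegistry | None = None,
    strict: bool = False,
    delimiter: str = "\t",
) -> BipartiteNet:
    """Read two-column (protein, domain) annotations into a BipartiteNet.

    With a supplied protein *registry*, rows naming unknown proteins are
    dropped with a warning, or rejected when ``strict`` is true. Without a
    registry, proteins register in order of first appearance.
    """
    own_registry = registry is None
    proteins = ProteinRegistry() if own_registry else registry
    domains = DomainRegistry()
    pairs: set[tuple[int, int]] = set()
    unknown: list[str] = []
    for _, (prot, dom) in _parse_rows(path, 2, delimiter):
        if not own_registry and prot not in proteins:
            unknown.append(prot)
            continue
        pairs.add((proteins.add(prot), domains.add(dom)))
    if unknown:
        if strict:
            raise ValueError(
                f"{path}: {len(unknown)} rows name proteins outside the PPI "
                f"universe: {sorted(set(unknown))[:10]}"
            )
        logger.warning(
            "%s: dropped %d domain rows for %d proteins outside the PPI universe",
            path, len(unknown), len(set(unknown)),
        )
    adj = np.zeros((len(proteins), len(domains)), dtype=np.uint8)
    for i, j in pairs:
        adj[i, j] = 1
    return BipartiteNet(proteins, domains, adj)


def write_pdi(net: BipartiteNet, path: str | Path, delimiter: str = "\t") -> None:
    """Write a BipartiteNet as a two-column (protein, domain) edge list."""
    with Path(path).open("w") as fh:
        rows, cols = np.nonzero(net.adjacency)
        for i, j in zip(rows.tolist(), cols.tolist()):
            fh.write(f"{net.proteins[i]}{delimiter}{net.domains[j]}\n")


def read_annotations(
    subcell_path: str | Path | None = None,
    ortho_path: str | Path | None = None,
    expr_path: str | Path | None = None,
    delimiter: str = "\t",
) -> AnnotationTable:
    """Read subcellular-localization, orthology and expression tables.

    Subcellular: (protein, compartment) rows. Orthology: (protein, count)
    rows with nonnegative integer counts. Expression: a header row of sample
    names followed by (protein, v1..vn) rows of equal arity.
    """
    table = AnnotationTable()
    if subcell_path is not None:
        vocab: list[str] = []
        for _, (prot, comp) in _parse_rows(subcell_path, 2, delimiter):
            table.subcellular.setdefault(prot, set()).add(comp)
            if comp not in vocab:
                vocab.append(comp)
        table.compartments = vocab
    if ortho_path is not None:
        for lineno, (prot, count) in _parse_rows(ortho_path, 2, delimiter):
            c = int(count)
            if c < 0:
                raise ValueError(f"{ortho_path}:{lineno}: negative ortholog count {c}")
            table.orthologs[prot] = c
    if expr_path is not None:
        n = None
        first = True
        for lineno, cols in _parse_rows(expr_path, 0, delimiter):
            if first:
                first = False
                n = len(cols) - 1  # header: "protein" + sample names
                if n < 2:
                    raise ValueError(f"{expr_path}: need at least 2 expression samples")
                continue
            if len(cols) - 1 != n:
                raise ValueError(
                    f"{expr_path}:{lineno}: ragged expression row "
                    f"({len(cols) - 1} values, expected {n})"
                )
            table.expression[cols[0]] = np.array([float(v) for v in cols[1:]])
        table.n_samples = n or 0
    return table


def read_essential(path: str | Path) -> set[str]:
    """Read a gold-standard essential-protein list (one ID per line)."""
    out: set[str] = set()
    for _, cols in _parse_rows(path, 0):
        out.add(cols[0])
    return out


def ranking_order(
    scores: np.ndarray,
    registry: ProteinRegistry,
    initial: np.ndarray | None = None,
) -> list[int]:
    """Deterministic ranking order: descending score, then descending
    initial score, then ascending protein ID."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (len(registry),):
        raise ValueError("score vector length must equal registry size")
    if not np.isfinite(scores).all():
        raise ValueError("scores contain NaN or Inf")
    init = np.zeros_like(scores) if initial is None else np.asarray(initial, float)
    order = sorted(
        range(len(registry)),
        key=lambda k: (-scores[k], -init[k], registry[k]),
    )
    return order


def write_ranking(
    scores: np.ndarray,
    registry: ProteinRegistry,
    path: str | Path,
    initial: np.ndarray | None = None,
    header: bool = True,
) -> list[str]:
    """Write a (rank, protein, score) TSV in descending score order.

    Returns the ranked protein IDs. Tie order is deterministic (see
    :func:`ranking_order`).
    """
    order = ranking_order(scores, registry, initial)
    ranked = [registry[k] for k in order]
    with Path(path).open("w") as fh:
        if header:
            fh.write("rank\tprotein\tscore\n")
        for r, k in enumerate(order, start=1):
            fh.write(f"{r}\t{registry[k]}\t{scores[k]:.10g}\n")
    return ranked


def read_ranking(path: str | Path) -> list[str]:
    """Read protein IDs, in rank order, from a ranking TSV (with or without
    header; one- or multi-column)."""
    ids: list[str] = []
    for lineno, cols in _parse_rows(path, 0):
        if lineno == 1 and cols[0].lower() in ("rank", "protein"):
            continue
        ids.append(cols[1] if len(cols) >= 2 and cols[0].isdigit() else cols[0])
    return ids
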