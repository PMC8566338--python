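"""Synthetic datasets: a 5x4 worked-example bipartite network and full
planted-signal datasets for end-to-end pipeline testing.

The full generator emulates the shapes of a yeast PPI study: a heavy-tailed
interaction network (preferential attachment), Pfam-style domain
annotations, an 11-compartment localization vocabulary, ortholog counts
against a panel of reference genomes, and a 36-sample expression matrix.
A planted fraction of proteins is labelled essential and receives the
signals the method exploits: higher degree (hence triangle participation),
enrichment in the nucleus- and mitochondrion-like compartments, more
ortholog hits, shared domain usage, and co-expression through a common
latent factor. Zeroing every effect size yields an exchangeable null in
which labels carry no signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .io import (
    AnnotationTable,
    BipartiteNet,
    DomainRegistry,
    PPINetwork,
    ProteinRegistry,
    write_pdi,
)

__all__ = ["toy_pdi", "ToyExpectations", "SynthSpec", "SyntheticDataset", "simulate"]

# mirrors the 11-compartment localization vocabulary of the yeast data
COMPARTMENTS = [
    "cytoskeleton", "mitochondrion", "nucleus", "peroxisome", "plasma",
    "extracellular", "endosome", "vacuole", "endoplasmic", "cytosol", "golgi",
]
ENRICHED = ("nucleus", "mitochondrion")


@dataclass(frozen=True)
class ToyExpectations:
    """Hand-derived collaborative-filtering quantities for the toy network."""

    smpp_p1_p3: float = 1.0 / math.sqrt(2.0)
    smpp_p1_p2: float = 0.5
    rmpd_p3_d1: float = 1.0 / math.sqrt(2.0)   # prints as 0.71
    rmpd_p2_d2: float = 0.5
    std_d1: float = (0.5 + 0.5 + 1.0 / math.sqrt(2.0) + 0.5) / 5.0  # 0.4414
    protein_side_added: tuple[tuple[str, str], ...] = (("p3", "d1"), ("p4", "d1"))
    domain_side_added: tuple[tuple[str, str], ...] = (("p1", "d3"),)


def toy_pdi() -> tuple[BipartiteNet, ToyExpectations]:
    """The fixed 5-protein / 4-domain worked-example bipartite network:
    p1={d1,d2}, p2={d1,d3}, p3={d2}, p4={d3,d4}, p5={d4}."""
    proteins = ProteinRegistry(["p1", "p2", "p3", "p4", "p5"])
    domains = DomainRegistry(["d1", "d2", "d3", "d4"])
    adj = np.array(
        [
            [1, 1, 0, 0],
            [1, 0, 1, 0],
            [0, 1, 0, 0],
            [0, 0, 1, 1],
            [0, 0, 0, 1],
        ],
        dtype=np.uint8,
    )
    return BipartiteNet(proteins, domains, adj), ToyExpectations()


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the planted-signal generator.

    Effect sizes at their neutral values (``degree_boost=1``,
    ``domain_bias=1``, ``compartment_bias=1``, equal ortholog rates,
    ``expr_coupling=0``) make the essential labels independent of every
    feature.
    """

    n_proteins: int = 300
    n_domains: int = 150
    attach_edges: int = 3          # preferential-attachment edges per new protein
    essential_frac: float = 0.2
    degree_boost: float = 2.0      # attachment-edge multiplier for essentials
    domains_per_protein: float = 2.0   # mean of 1 + Poisson
    domain_pool_frac: float = 0.25     # essentials prefer this leading slice of domains
    domain_bias: float = 3.0           # preference weight (1 = none)
    compartment_bias: float = 4.0      # nucleus/mitochondrion weight for essentials
    n_genomes: int = 100
    ortho_p_essential: float = 0.7
    ortho_p_background: float = 0.3
    n_samples: int = 36
    expr_coupling: float = 0.8     # essentials' loading on the shared latent factor
    expr_noise: float = 1.0
    seed: int = 0

    def null(self) -> "SynthSpec":
        """The zero-effect-size twin of this spec (same sizes and seed)."""
        return replace(
            self,
            degree_boost=1.0,
            domain_bias=1.0,
            compartment_bias=1.0,
            ortho_p_essential=self.ortho_p_background,
            expr_coupling=0.0,
        )


@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset in the package's standard containers."""

    ppi: PPINetwork
    pdi: BipartiteNet
    annotations: AnnotationTable
    essential: set[str]
    spec: SynthSpec

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the five standard input files; returns their paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "ppi": outdir / "ppi.tsv",
            "pdi": outdir / "pdi.tsv",
            "subcell": outdir / "subcellular.tsv",
            "ortho": outdir / "orthologs.tsv",
            "expr": outdir / "expression.tsv",
            "essential": outdir / "essential.txt",
        }
        with paths["ppi"].open("w") as fh:
            for i, j in sorted(self.ppi.edges):
                fh.write(f"{self.ppi.registry[i]}\t{self.ppi.registry[j]}\n")
        write_pdi(self.pdi, paths["pdi"])
        with paths["subcell"].open("w") as fh:
            for p in self.ppi.registry:
                for c in sorted(self.annotations.subcellular.get(p, ())):
                    fh.write(f"{p}\t{c}\n")
        with paths["ortho"].open("w") as fh:
            for p in self.ppi.registry:
                fh.write(f"{p}\t{self.annotations.orthologs.get(p, 0)}\n")
        with paths["expr"].open("w") as fh:
            header = "\t".join(f"s{i + 1}" for i in range(self.annotations.n_samples))
            fh.write(f"protein\t{header}\n")
            for p in self.ppi.registry:
                vec = self.annotations.expression[p]
                fh.write(p + "\t" + "\t".join(f"{v:.6f}" for v in vec) + "\n")
        with paths["essential"].open("w") as fh:
            for p in self.ppi.registry:
                if p in self.essential:
                    fh.write(p + "\n")
        return paths


def _pa_graph(spec: SynthSpec, essential_mask: np.ndarray, rng: np.random.Generator) -> set[tuple[int, int]]:
    """Preferential-attachment edge set; essentials attach with more edges."""
    n, m = spec.n_proteins, spec.attach_edges
    edges: set[tuple[int, int]] = set()
    degree = np.zeros(n)
    seed_size = m + 1
    for i in range(seed_size):
        for j in range(i + 1, seed_size):
            edges.add((i, j))
            degree[i] += 1
            degree[j] += 1
    for u in range(seed_size, n):
        m_u = max(1, int(round(m * (spec.degree_boost if essential_mask[u] else 1.0))))
        m_u = min(m_u, u)
        weights = degree[:u] + 1.0
        targets = rng.choice(u, size=m_u, replace=False, p=weights / weights.sum())
        for v in targets:
            v = int(v)
            edges.add((v, u))
            degree[u] += 1
            degree[v] += 1
    return edges


def simulate(spec: SynthSpec) -> SyntheticDataset:
    """Generate one seeded, fully reproducible synthetic dataset."""
    n_ess = math.floor(spec.essential_frac * spec.n_proteins)
    if n_ess < 1:
        raise ValueError("essential_frac * n_proteins must be at least 1")
    rng = np.random.default_rng(spec.seed)

    ids = [f"P{k:04d}" for k in range(spec.n_proteins)]
    registry = ProteinRegistry(ids)
    essential_idx = rng.choice(spec.n_proteins, size=n_ess, replace=False)
    mask = np.zeros(spec.n_proteins, dtype=bool)
    mask[essential_idx] = True
    essential = {ids[k] for k in np.flatnonzero(mask)}

    ppi = PPINetwork(registry, _pa_graph(spec, mask, rng))

    # domain annotations: essentials draw from a biased pool of shared domains
    domains = DomainRegistry([f"PF{j:05d}" for j in range(spec.n_domains)])
    pool = max(1, int(spec.domain_pool_frac * spec.n_domains))
    w_ess = np.ones(spec.n_domains)
    w_ess[:pool] = spec.domain_bias
    w_ess /= w_ess.sum()
    w_bg = np.full(spec.n_domains, 1.0 / spec.n_domains)
    adj = np.zeros((spec.n_proteins, spec.n_domains), dtype=np.uint8)
    for k in range(spec.n_proteins):
        n_dom = 1 + rng.poisson(spec.domains_per_protein - 1.0)
        n_dom = min(n_dom, spec.n_domains)
        chosen = rng.choice(
            spec.n_domains, size=n_dom, replace=False, p=w_ess if mask[k] else w_bg
        )
        adj[k, chosen] = 1
    pdi = BipartiteNet(registry, domains, adj)

    ann = AnnotationTable(compartments=list(COMPARTMENTS), n_samples=spec.n_samples)
    enriched_pos = [COMPARTMENTS.index(c) for c in ENRICHED]
    for k in range(spec.n_proteins):
        w = np.ones(len(COMPARTMENTS))
        if mask[k]:
            for pos in enriched_pos:
                w[pos] = spec.compartment_bias
        w /= w.sum()
        n_comp = min(1 + rng.poisson(0.8), 4)
        comps = rng.choice(len(COMPARTMENTS), size=n_comp, replace=False, p=w)
        ann.subcellular[ids[k]] = {COMPARTMENTS[c] for c in comps}
        p_hit = spec.ortho_p_essential if mask[k] else spec.ortho_p_background
        ann.orthologs[ids[k]] = int(rng.binomial(spec.n_genomes, p_hit))

    latent = rng.normal(size=spec.n_samples)
    for k in range(spec.n_proteins):
        noise = rng.normal(size=spec.n_samples) * spec.expr_noise
        coupling = spec.expr_coupling if mask[k] else 0.0
        ann.expression[ids[k]] = coupling * latent + noise

    return SyntheticDataset(ppi, pdi, ann, essential, spec)
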