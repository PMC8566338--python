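"""End-to-end orchestration: files in, ranking (and metrics) out.

Stages: read inputs -> collaborative-filtering densification of the
protein-domain network -> GIP-kernel PPI weighting -> feature scoring and
entropy-weight fusion -> damped propagation -> ranking -> optional
evaluation against a gold standard.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cf, evaluation, features, kernel, ranking as rk
from .io import (
    AnnotationTable,
    BipartiteNet,
    PPINetwork,
    read_annotations,
    read_essential,
    read_pdi,
    read_ppi,
    write_ranking,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "run_from_config", "parameter_sweep"]


@dataclass
class RunConfig:
    """All file paths and tunables of one end-to-end run."""

    ppi_path: str = ""
    pdi_path: str = ""
    subcell_path: str | None = None
    ortho_path: str | None = None
    expr_path: str | None = None
    essential_path: str | None = None
    output_path: str | None = None

    alpha: float = 0.9
    lam: float = 0.65
    delta_prime: float = 1.0
    eps: float = 1e-6
    max_iter: int = 100
    cf_iterations: int = 1
    normalize_rows: bool = True
    mask_wp_to_ppi: bool = True
    strict: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {self.lam}")
        if self.eps <= 0:
            raise ValueError("eps must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class PipelineResult:
    """Everything one run produces, for inspection or serialization."""

    ranking: list[str]
    scores: np.ndarray
    feature_table: features.FeatureTable
    cf_result: cf.CFResult
    weighted: kernel.WeightedPPI
    iteration: rk.IterationResult
    report: evaluation.EvalReport | None = None
    scores_by_id: dict[str, float] = field(default_factory=dict)


def run_pipeline(
    ppi: PPINetwork,
    pdi: BipartiteNet,
    annotations: AnnotationTable,
    essential: set[str] | None = None,
    alpha: float = 0.9,
    lam: float = 0.65,
    delta_prime: float = 1.0,
    eps: float = 1e-6,
    max_iter: int = 100,
    cf_iterations: int = 1,
    normalize_rows: bool = True,
    mask_wp_to_ppi: bool = True,
) -> PipelineResult:
    """Run the full method on in-memory inputs."""
    cf_res = cf.run_cf(pdi, iterations=cf_iterations)
    logger.info("collaborative filtering added %d edges", cf_res.n_added)
    weighted = kernel.build_weighted_ppi(
        cf_res.mrm, ppi, delta_prime=delta_prime, mask_wp_to_ppi=mask_wp_to_ppi
    )
    ft = features.compute_features(ppi, annotations, lam=lam)
    logger.info("entropy weights: %s", np.round(ft.weights, 4))
    drpm = rk.build_drpm(weighted.wp, ft.proscore, normalize_rows=normalize_rows)
    it = rk.iterate(drpm, ft.proscore, alpha=alpha, eps=eps, max_iter=max_iter)
    logger.info(
        "propagation: %d iterations, converged=%s, residual=%.3g",
        it.n_iter, it.converged, it.residual,
    )
    ranked = rk.rank(it.scores, ppi.registry, initial=ft.proscore)
    by_id = {ppi.registry[k]: float(it.scores[k]) for k in range(ppi.n)}
    report = None
    if essential is not None:
        report = evaluation.evaluate_ranking(ranked, by_id, essential)
    return PipelineResult(ranked, it.scores, ft, cf_res, weighted, it, report, by_id)


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"stage '{name}' failed: {exc}") from exc


def run_from_config(config: RunConfig) -> PipelineResult:
    """Run the full method from files per a RunConfig; optionally write the
    ranking TSV."""
    ppi = _stage("read_ppi", read_ppi, config.ppi_path)
    pdi = _stage("read_pdi", read_pdi, config.pdi_path, ppi.registry, config.strict)
    ann = _stage(
        "read_annotations",
        read_annotations,
        config.subcell_path,
        config.ortho_path,
        config.expr_path,
    )
    essential = read_essential(config.essential_path) if config.essential_path else None
    result = run_pipeline(
        ppi,
        pdi,
        ann,
        essential,
        alpha=config.alpha,
        lam=config.lam,
        delta_prime=config.delta_prime,
        eps=config.eps,
        max_iter=config.max_iter,
        cf_iterations=config.cf_iterations,
        normalize_rows=config.normalize_rows,
        mask_wp_to_ppi=config.mask_wp_to_ppi,
    )
    if config.output_path:
        write_ranking(
            result.scores, ppi.registry, config.output_path,
            initial=result.feature_table.proscore,
        )
    return result


def parameter_sweep(
    ppi: PPINetwork,
    pdi: BipartiteNet,
    annotations: AnnotationTable,
    essential: set[str],
    alphas: list[float],
    lams: list[float] | None = None,
    percents=evaluation.DEFAULT_PERCENTS,
    **kwargs,
) -> list[dict]:
    """Grid-evaluate (alpha, lambda) combinations; one row of top-k hit
    counts per combination, in the layout of a sweep table."""
    lams = lams or [kwargs.pop("lam", 0.65)]
    rows: list[dict] = []
    for lam in lams:
        for alpha in alphas:
            res = run_pipeline(
                ppi, pdi, annotations, essential, alpha=alpha, lam=lam, **kwargs
            )
            row = {"alpha": alpha, "lambda": lam}
            for p, block in res.report.topk.items():
                row[f"top_{p}pct_hits"] = block["hits"]
                row[f"top_{p}pct_cutoff"] = block["cutoff"]
            rows.append(row)
    return rows
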