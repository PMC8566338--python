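"""Full pipeline on a planted-signal synthetic dataset.

Simulates a 300-protein network in which 20% of proteins are labelled
essential and carry the signals the method exploits (higher degree, shared
domains, nucleus/mitochondrion enrichment, more orthologs, co-expression),
then ranks all proteins and scores the ranking against the planted labels.
"""

from essrank import SynthSpec, run_pipeline, simulate

spec = SynthSpec(n_proteins=300, n_domains=150, essential_frac=0.2, seed=7)
ds = simulate(spec)
print(f"simulated {ds.ppi.n} proteins, {len(ds.ppi.edges)} interactions, "
      f"{int(ds.pdi.adjacency.sum())} domain annotations, "
      f"{len(ds.essential)} planted essentials")

res = run_pipeline(ds.ppi, ds.pdi, ds.annotations, ds.essential,
                   alpha=0.9, lam=0.65)
print(f"collaborative filtering added {res.cf_result.n_added} edges")
print(f"entropy weights (ProSub, ProOrt, ProExp): "
      f"{[round(float(w), 3) for w in res.feature_table.weights]}")
print(f"propagation converged in {res.iteration.n_iter} iterations "
      f"(residual {res.iteration.residual:.2e})")

# precision among the top-ranked slices: how many of the proteins the
# method puts first really carry the essential label
for p, blk in res.report.topk.items():
    print(f"top {p:>4}% (first {blk['cutoff']:>3} proteins): "
          f"{blk['precision']:.1f}% essential")
print(f"AUC against planted labels: {res.report.auc:.4f} "
      f"(0.5 would be chance)")

# the zero-effect twin of the same spec: labels carry no signal
ds0 = simulate(spec.null())
res0 = run_pipeline(ds0.ppi, ds0.pdi, ds0.annotations, ds0.essential)
print(f"same pipeline on the zero-effect null: AUC {res0.report.auc:.4f}")
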