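# Methods

## Model

The ranking pipeline treats essential-protein prediction as score
propagation on a weighted PPI network, where both the edge weights and the
restart distribution are built from data beyond raw topology.

### Densifying the protein–domain network

Domain annotation is incomplete, so the binary protein × domain adjacency
is densified before use. The step is an item/user-style recommender run
from both sides of the bipartite graph. Similarity between two proteins is
the cosine of their binary domain profiles (shared-domain count over the
geometric mean of their annotation counts); zero-degree entities get
similarity 0 to everything, the limit value, avoiding a 0/0. The
recommendation score of every (protein, domain) cell is the
similarity-weighted vote of all annotated proteins, `R = S·A`, and a new
edge is added where the score *strictly* exceeds the column mean of `R`.
The threshold is one scalar per domain column: the column mean over all N
rows, zeros included. Strict inequality means a column whose entries are
all equal yields no recommendations.

Both passes start from the *original* adjacency — they are independent, not
chained — and merge by union (for binary matrices the sum-capped-at-one
combination is exactly logical OR). The merge can only add edges, so the
mutual recommendation matrix dominates the input element-wise; provenance
of each added edge (protein-side / domain-side) is kept for inspection.
Iterating the whole step to a fixed point is exposed as a config knob but
defaults to a single pass, the standard procedure.

### Kernel weights

Protein i's interaction profile is row i of the mutual recommendation
matrix. Pairwise weights use the Gaussian interaction-profile kernel
`exp(−δ‖IP(i)−IP(j)‖²)` with bandwidth normalized by the mean squared
profile norm, `δ = δ′ / mean‖IP‖²`, making δ scale-free in the number of
domains; δ′ defaults to 1. For binary profiles the squared distance is the
Hamming distance, so the kernel is a strictly decreasing function of
annotation disagreement, equals 1 exactly for identical profiles, and is
always positive.

The propagation stage uses `WP = WBP·(1+max)/2` with `max` the global
off-diagonal maximum of the kernel matrix — a single mild rescale — masked
to the PPI edge set so score flows only along observed interactions. Both
the rescale and the mask are configurable (`rescale`, `mask_wp_to_ppi`);
the mask is the default because the propagation walks PPI neighborhoods.

### Feature scores and fusion

* **ProSub** — compartments are weighted by how many proteins they house
  relative to the average compartment (essential proteins concentrate in
  populous compartments such as the nucleus and mitochondrion); a protein
  sums the weights of its compartments. Unannotated proteins score 0.
* **ProOrt** — ortholog-genome count divided by the network-wide maximum;
  all-zero input is guarded to all-zero output.
* **ProExp** — sum of sample Pearson correlation (1/(n−1), sample SDs) to
  PPI neighbors. Constant expression vectors get correlation 0 (undefined
  correlation treated as no evidence). Negative sums are floored at 0
  before max-normalization: a negative "functional score" would corrupt
  the entropy step, which needs nonnegative inputs.
* **ProTri** — for each protein, the sum over neighbors of shared-neighbor
  counts divided by its degree; algebraically 2·(triangles through the
  node)/degree. Max-normalized before blending so both terms of the final
  blend share the [0,1] scale.

The three biological columns are min–max scaled, then entropy-weighted:
each column becomes proportions (0/0 → 0), its Shannon entropy is
normalized by ln N with 0·ln 0 := 0, and weights are `w_j ∝ 1−e_j`.
A constant (maximal-entropy) column is kept as-is by the min–max step so
its proportions stay uniform and its weight is exactly 0; if *every*
column is maximal-entropy the weights fall back to uniform. The (1−e)
terms are clamped at zero before normalizing because rounding can push an
entropy a few ulps past 1.

The initial score is the convex blend `λ·proBio + (1−λ)·ProTri`, rescaled
to sum 1 so it can serve directly as the restart distribution (the rescale
does not affect the distribution-rate matrix, which is scale-invariant in
the initial score).

### Propagation

The distribution-rate matrix carries `W(k,r)·proscore(r)` over the sum of
neighbor scores for PPI edges and 0 elsewhere. Rows are normalized to sum 1
by default: the raw form is not stochastic (the numerator carries the edge
weight), and normalization makes the damped iteration a contraction with
factor ≤ α, guaranteeing geometric convergence; the un-normalized form
remains available via `normalize_rows=False` for fidelity experiments.
Rows with no support (isolated proteins, or neighborhoods whose scores sum
to 0) stay all-zero; they leak score mass that the `(1−α)·s(0)` restart
term replenishes, so no extra dangling-node redistribution is added.

The iteration `s ← α·s·D + (1−α)·s(0)` runs as a row vector multiplying D
on the left, stopping when the L2 step norm drops below ε (default 1e−6,
max 100 iterations). At termination the fixed-point residual is below
10·ε, and with a fully stochastic D total score mass is conserved to
1e−12 — both asserted in tests. Defaults α = 0.9 and λ = 0.65 follow the
sweep-selected operating point for sparse binary-interaction networks;
λ = 0.8 is the preset for denser complex-derived networks. Final ties
break by descending initial score, then ascending protein ID, so output is
fully deterministic.

## Evaluation machinery

Top-k% precision uses cutoff ceil(p/100·N) — the only rounding rule
consistent with the familiar cutoffs 51 (1%) and 1,274 (25%) at N = 5,093.
Gold-standard proteins outside the ranked universe are dropped with a
warning, so denominators are in-network cutoffs. The jackknife curve is the
cumulative count of true essentials among the top r, to depth 1,000 by
default. ROC/PR/AUC go through scikit-learn; AUC is the Mann–Whitney
statistic with rank-averaged ties, cross-checked in tests against a
pair-counting oracle. Overlap statistics between two methods' top-k sets
report the intersection, both difference sets, and the essential fraction
within each difference.

## Synthetic data

The generator emulates the shapes of a yeast PPI study: N = 300 proteins
(M = 150 domains) by default, a preferential-attachment interaction
network (m = 3 edges per arriving node; heavy-tailed like real PPI data),
an 11-compartment localization vocabulary, ortholog counts against a
100-genome panel, and a 36-sample expression matrix. A planted 20%
essential fraction receives every signal the method exploits:

* 2× attachment edges (degree and triangle enrichment),
* domain draws biased 3× toward a shared leading quarter of domains
  (profile similarity → kernel signal),
* 4× compartment weight on the nucleus- and mitochondrion-like
  compartments,
* Binomial(100, 0.7) ortholog hits versus Binomial(100, 0.3) background,
* expression coupled to a shared latent factor with loading 0.8 over
  unit noise.

These effect sizes were fixed once as plausible, clearly-separated yet
noisy signals for a network of this size; `SynthSpec.null()` zeroes all of
them, making labels exchangeable. The same seed yields byte-identical
files. What the simulation does **not** emulate: the quantitative degree
distributions of curated interaction databases, annotation biases
correlated between sources, false-positive interaction structure, or
ID-mapping noise — so passing tests demonstrate correct mechanics and
planted-signal recovery, not field performance on curated yeast data.

## Problem sizes and numerical choices

Tests run the full pipeline at N = 120–300, where a run takes well under a
second; the planted-signal acceptance check runs 20 paired
(effect vs null) simulations at N = 300 and compares AUCs with a paired
sign test. Dense float64 matrices are used throughout — at the scale of
real yeast networks (N ≈ 5,000) the largest objects are ~200 MB, well
within a workstation's memory; sparse variants were deliberately left out
to keep the kernel and propagation code transparent. Distances in the
kernel use the Gram expansion, exact for binary profiles after clamping
tiny negatives at 0.

## Known limitations

* Zero-imputation for proteins missing from an annotation source is a
  choice, not a fact of the data; it is conservative but can depress the
  ranking of sparsely annotated proteins.
* The global-maximum reading of the WP rescale and the PPI-edge mask are
  interpretations of an underspecified transform; both are configurable.
* With `normalize_rows=False` the iteration may converge slowly or not at
  all for α near 1; the default configuration is the supported one.
* The collaborative-filtering step is purely binary; no rating-style or
  factorization variants are implemented.
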