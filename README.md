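# essrank

Essential proteins are those whose loss is lethal to an organism; finding
them computationally from protein–protein interaction (PPI) networks is a
long-standing problem in systems biology, because knockout screens are slow
and expensive. `essrank` implements a ranking method that addresses the two
classic weaknesses of centrality-style predictors — incomplete interaction
data and reliance on topology alone — by (1) densifying the protein–domain
annotation network with a recommender-system step before using it, and
(2) fusing topology with independent biological evidence.

It is a library first (importable API plus `examples/` scripts) with a thin
`essrank` command-line tool on top, aimed at computational biologists who
have a PPI edge list, Pfam-style domain annotations, and optional
localization / orthology / expression tables.

## The method

**1. Collaborative filtering on the protein–domain network.** With binary
adjacency `A` (proteins × domains), protein similarity is the cosine of
annotation profiles,

```
S(i,j) = |N(i) ∩ N(j)| / sqrt(|N(i)|·|N(j)|)   (i ≠ j, 0 on the diagonal)
```

and the recommendation matrix is `R = S·A`. A cell (k, j) with `A(k,j)=0`
becomes a new edge when `R(k,j)` strictly exceeds the column mean
`Std(j) = mean_i R(i,j)`. The same step runs from the domain side on `Aᵀ`,
and the two updated adjacencies merge by union into the mutual
recommendation matrix `MRM ≥ A` (edges are only added, never removed).

**2. Kernel weighting of the PPI network.** Each protein's row of `MRM` is
its interaction profile `IP(i)`; edges are weighted with the Gaussian
interaction-profile kernel

```
W(i,j) = exp(−δ · ‖IP(i) − IP(j)‖²),   δ = δ′ / mean_i ‖IP(i)‖²
```

then mildly rescaled by `(1 + max offdiag W)/2` and masked to the PPI edge
set.

**3. Feature fusion.** Three biological scores per protein — subcellular
localization weight (sum over the protein's compartments of
compartment-count / average-count), max-normalized ortholog count, and
neighbor co-expression (sum of Pearson correlation to PPI neighbors,
floored at 0, max-normalized) — are min–max scaled and fused with entropy
weights (`w_j ∝ 1 − e_j`, where `e_j` is the normalized Shannon entropy of
feature column j; constant features get weight 0). The fused biology blends
with a triangle topology score (twice the triangles through a node over its
degree, max-normalized):

```
proscore(k) = λ·proBio(k) + (1−λ)·ProTri(k),   λ ∈ [0,1]
```

**4. Damped propagation.** A distribution-rate matrix spreads score along
weighted edges in proportion to the target's initial score,
`D(k,r) ∝ W(k,r)·proscore(r)` (row-normalized), and the ranking comes from
the fixed point of

```
s(t+1) = α·s(t)·D + (1−α)·s(0),   α ∈ (0,1)
```

iterated until the L2 step norm falls below ε. Defaults: α = 0.9, λ = 0.65
(a λ = 0.8 preset suits denser complex-derived networks), δ′ = 1,
ε = 1e−6.

## Worked example

`python examples/01_worked_example.py` walks the 5-protein / 4-domain toy
network (p1={d1,d2}, p2={d1,d3}, p3={d2}, p4={d3,d4}, p5={d4}) through the
recommendation step and prints:

```
RM(p3,d1) = 0.7071 > Std(d1) = 0.4414 -> recommend p3 to d1
RM(p4,d1) = 0.5000 > Std(d1) = 0.4414 -> recommend p4 to d1
```

p3 shares domain d2 with p1, an annotator of d1, with cosine similarity
1/√2 ≈ 0.71; that vote exceeds d1's column-mean standard 0.44, so the edge
(p3, d1) is added. `RM(p2,d2) = 0.5` stays a single similarity vote.

`python examples/02_synthetic_pipeline.py` runs the full pipeline on a
300-protein planted-signal simulation and prints:

```
collaborative filtering added 3422 edges
entropy weights (ProSub, ProOrt, ProExp): [0.22, 0.143, 0.637]
propagation converged in 19 iterations (residual 5.68e-07)
top    1% (first   3 proteins): 66.7% essential
AUC against planted labels: 0.8809 (0.5 would be chance)
same pipeline on the zero-effect null: AUC 0.4261
```

The AUC of 0.88 against the planted labels (versus ~0.5 for the
signal-free null) shows the pipeline recovering the planted degree,
localization, orthology, co-expression and domain-sharing signals.

## Command line

```
essrank simulate --n 300 --m 150 --essential-frac 0.2 --seed 7 -o data/
essrank rank --ppi data/ppi.tsv --pdi data/pdi.tsv \
    --subcell data/subcellular.tsv --ortho data/orthologs.tsv \
    --expr data/expression.tsv --essential data/essential.txt \
    --alpha 0.9 --lam 0.65 -o ranking.tsv
essrank evaluate --ranking ranking.tsv --essential data/essential.txt -o report.json
essrank sweep --ppi ... --alphas 0.1,0.5,0.9 -o sweep.csv
```

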