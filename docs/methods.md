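# Methods

This note records the models, numerical choices and study conditions behind
`cofembed`, in the order of the pipeline. It documents decisions; every
empirical number it mentions is computed by the test suite or by
`scripts/acceptance.py`, not asserted here.

## Preprocessing

**Expression.** Genes detected in fewer than 3 cells are removed; counts are
scaled per cell to a common library size — the *median* of per-cell totals,
a scale-free choice that keeps values in the raw count range — then mapped
through log(1+x) (natural log). Both maps are monotone within a cell, so
within-cell gene ranking is preserved.

**Discretization.** The non-zero normalized values are partitioned into
n = 5 expression levels by one-dimensional k-means. Because an optimal 1-D
clustering is a contiguous partition of the sorted values, we solve it
*exactly* with a weighted dynamic program over unique values; above 2,048
distinct values the data are first pooled into 2,048 weighted quantile bins,
keeping the procedure deterministic and near-optimal at bounded cost. Levels
are labeled 1..n by ascending cluster mean; zeros are excluded from boundary
estimation and always map to level 0; a value exactly on a boundary maps to
the lower level. Iterative Lloyd refinement was considered and rejected: it
is sensitive to initialization and not guaranteed optimal, while the DP is
both exact and fast at these sizes.

**Variable features.** Genes are ranked by mean-binned normalized
dispersion: dispersion = variance/mean of the normalized values, z-scored
within 20 quantile bins of mean expression (quantile rather than equal-width
bins keep occupancy even, so no gene is z-scored against itself); the top
2,000 are kept by default and constant genes are never selected. Variances
are computed as E[x²]−E[x]² with residues below the float cancellation scale
(10⁻¹⁰·mean²) clamped to zero. Peaks are selected by truncated SVD: the
number of retained components is read off the elbow of the
explained-variance curve, and within each component the peaks whose absolute
loadings fall before the knee of the descending sorted-loadings curve are
kept (union over components). Both the elbow and the knee use the same rule:
maximum distance to the chord of the curve normalized to the unit square;
a flat curve has no knee and contributes nothing.

**Sequence features.** k-mer presence (default k = 6) is exact string
matching on the forward strand, with optional reverse-complement
canonicalization; windows containing non-ACGT characters are skipped, and
sequences shorter than k give all-zero rows. Motif presence uses a
simplified scanner: log-odds of the PWM against a uniform background
(pseudocount 10⁻³), with a hit when the best window reaches 80% of the
motif's maximum achievable score. This is deliberately conservative and
simple; it is not intended to reproduce any particular external scanner's
match set.

## Graph construction

Entities are typed (cells of each batch/modality, genes, peaks, k-mers,
motifs, null features); every relation fixes a source type, a destination
type and a weight. Expression level ℓ of n maps to its own relation with
weight spaced evenly so level 1 has weight 1.0 and level n has 5.0 (for the
default n = 5: 1, 2, 3, 4, 5). An alternative single-relation mode encodes
the expression value directly as the per-edge weight. Accessibility uses
one cell–peak relation at weight 1.0, with peak–k-mer at 0.02 and
peak–motif at 0.2 — sequence features are numerous and individually weak,
hence the small weights. Graphs combine by merging equally named entity
types on their id union; ids must be globally unique across types.

**Inferred cell–cell edges.** For two datasets over m shared feature
columns, X = X1·X2ᵀ is factored by randomized SVD (d = 20 components,
oversampling 10, 4 power iterations, seeded); rows of U and V are
L2-normalized and a pair is kept iff each side is within the other's k = 20
nearest neighbors (exact Euclidean search; monotone in cosine after
normalization). With more than two batches, edges are inferred between the
largest batch (the hub) and every other batch. The inferred relation weight
defaults to 1.0 and is configurable; the choice matters little on the
synthetic conditions tested.

**Gene activity scores.** For each gene, peaks whose midpoint is within
100 kb of the TSS contribute their per-cell values: weight 1.0 if the peak
interval overlaps the gene body or the strand-aware 5 kb upstream flank,
else exp(−|midpoint − TSS|/5000). The weighted sum is divided by the gene's
body length relative to the median body length, so long genes do not win by
footprint alone. Coordinates are 0-based half-open; TSS is the body start
(+) or last base (−).

**Null features.** Significance needs features that carry each node's
degree bias but no biology. For a target type, `multiplier`×n null copies
are added (20× genes for expression, 5× peaks for accessibility by
convention): each full round replays the type's edges with the target
endpoint sent through a permutation that only maps between equal-degree
nodes — drawn once per round and shared across the parallel level
relations, so each null node's *total* degree equals a real node's total
degree exactly — and the opposite endpoint sent through a degree-preserving
permutation of its own type, which destroys connectivity. Null types are
flagged fixed: their edges update only null rows during training.

## Embedding trainer

Embeddings (D = 50) are initialized uniformly in ±1/√D from the run seed.
Each positive edge is contrasted with 200 typed corruptions (100 uniform,
100 degree-proportional within the correct type; the positive may re-occur
by chance and is kept, as in sampled-softmax practice) under the weighted
multi-class log loss with a numerically stable logsumexp. Updates are
row-wise Adagrad (base rate 0.1; accumulator = running mean-square of the
row's aggregated batch gradient; eps 10⁻¹⁰), batch size 1,024, edge order
reshuffled each epoch from the run seed, 10 epochs by default with optional
early stopping when the validation loss stops improving (patience 2). The
hot loop is a numba kernel; a vectorized numpy implementation of the same
update is kept as the fallback and reference.

**Weight decay.** L2 decay is amortized: once every `wd_interval` = 50
batches, the rows touched by that batch are shrunk by the proximal step
θ ← θ/(1 + η_row·λ) with λ = wd × wd_interval (the proximal form is stable
for any λ). `wd` defaults to C/N_e with N_e the number of training edges
and C = 6000, set by monitoring train/validation loss curves on the
synthetic study conditions (~10⁵ edges): weaker decay lets the validation
loss climb from the first epoch, stronger decay costs training fit. C is
fully configurable and should be re-examined for graph scales far from
10⁵–10⁶ edges; note that graphs processed in fewer than `wd_interval`
batches per epoch apply decay rarely, so small-graph runs should lower
`wd_interval` accordingly.

**Fixed-type masking.** For any edge (or corruption of it) whose relation
touches a fixed entity type, gradient contributions to non-fixed rows are
dropped before aggregation; decay likewise only ever touches rows that
received gradient. A graph whose edges all touch fixed entities therefore
leaves real rows bitwise at initialization.

**Evaluation.** 5% of edges are held out uniformly (every relation keeps at
least one training edge). Each positive is ranked among its 200 sampled
candidates with pessimistic ties (a tying candidate counts against the
positive). Ranking uses the *filtered* protocol standard in link-prediction
evaluation: sampled candidates that are themselves observed associations of
the graph — at any parallel relation for the same node pair, e.g. another
expression level — are excluded from the rank, so the model is not punished
for scoring a true association highly. The validation *loss* keeps all
candidates, mirroring training. Reported MRR/R1/R10/R50/AUC are averaged
over three independent candidate draws to damp sampling noise; AUC counts
ties as one half. The random-rank MRR baseline among 201 candidates is
Σ(1/r)/201 ≈ 0.029.

## Softmax transformation

Features (and non-anchor cells) are re-expressed as convex combinations of
reference cell embeddings with weights ∝ p^(1/T), computed in log space as
softmax(logits/T) so sharp profiles cannot underflow; T = 0.5 by default.
Reference = all cells of the anchor type (the hub batch in multi-batch
settings), configurable. T → 0 snaps each query to its most probable
reference cell; T → ∞ gives the reference mean; a single reference cell is
an exact identity at any T.

## Specificity metrics and significance

Per feature, the dot products x over all reference cells give: max score =
mean of the top k = 50 of norm(x_i) = x_i − log(mean exp(x)) (shift
invariant; exactly 0 on constant profiles); s.d. with the n−1 denominator;
and Gini index and entropy of the probability profile (softmax of x at
temperature 1 by default, configurable to the T = 0.5 profile). The Gini
sum Σ(2i−n−1)p_(i)/(nΣp) is evaluated on ascending-sorted p (the formula
presumes order statistics); entropy uses the natural log with 0·log 0 = 0.
Empirical one-sided p-values against the trained null features use the +1
correction, p = (1+#{null ≥ obs})/(1+#null), with the tail reversed for
entropy (low entropy = specific); Benjamini–Hochberg FDR per metric. The
default reported pair is max score and Gini index.

## Queries and regulatory inference

Neighbor queries are exact Euclidean searches on a k-d tree over the
(optionally type-filtered) entity set, self-excluded, ties broken by id.
Distances for regulation are computed in the softmax-transformed space.
For each candidate master regulator (motif, gene), the TF gene's
competition rank (ties share the minimum) among all genes by distance to
the motif is reported; pairs below the 50th percentile of max score or Gini
within their own feature kind are flagged — not dropped — and the report is
sorted by gene rank. Target genes: candidates are the union of the 200
nearest genes to the motif and to the TF gene; a candidate must have a
motif-bearing peak within 100 kb of its TSS; its four distance ranks
(gene↔TF gene, gene↔TF motif, best nearby peak↔TF motif, best nearby
peak↔TF gene) are averaged with equal weights (configurable), and it passes
when the best peak rank is within 1,000 and the average rank within 5,000.

## Synthetic study conditions

The generator emulates a joint expression/accessibility assay with discrete
cell types and is the basis of every quantitative test. Defaults (all
overridable, all logged into the truth object):

| parameter | default | rationale |
|---|---|---|
| types × cells | 3 × 300 | desk-scale population with clear subtypes |
| genes / markers per type | 600 / 30 | marker fraction ~15% |
| peaks / per marker gene | 1,500 / 2 | marker peaks within 100 kb of their gene's TSS |
| baseline gene mean | log-normal, median 0.04, σ = 1.2 | heavy-tailed means; ~95% background zeros, as in droplet data |
| marker mean (own type) | 5.0 | detected in most cells of the type |
| NB dispersion (shape) | 4.0 | moderate overdispersion |
| per-cell depth jitter | log-normal σ = 0.25 | library-size variation |
| background open rate | log-normal, median 1.5%, cap 20% | sparse accessibility with propensity spread |
| marker peak open rate (own type) | 0.9 | strong accessibility signal |
| peak length / motif length | 200 bp / 8 bp | typical peak width; one planted motif per type, inserted into that type's marker peaks, with the type's first marker gene as the TF gene |

Batches are iid within-type splits with multiplicative log-normal per-gene
(σ = 0.3) and per-cell (σ = 0.2) distortions, rounded back to counts; the
identity effect leaves counts untouched.

What the generator does *not* emulate: ambient RNA, doublets, Tn5 sequence
bias, continuous differentiation trajectories, correlated gene programs
beyond the planted markers, or chromosome-scale structure beyond a uniform
gene pitch. Passing tests therefore demonstrate that the machinery recovers
planted discrete structure under realistic sparsity — not performance on
real tissue.

## Problem sizes and determinism

The test suite and acceptance workflow run the full multiome at the
3×300-cell scale (≈1.4×10⁵ edges, minutes per training on one CPU), the
two-batch correction at the same scale, and the null-calibration at
300 cells × 80 genes with 20× nulls; unit tests use miniatures. All
randomness flows from explicit seeds (generation, splitting, sampling,
initialization, epoch shuffling), so a fixed seed reproduces Θ bitwise.

## Known limitations

- The dot-product comparator is the only scorer; no per-relation operators.
- Single-process training only; graphs beyond ~10⁷ edges will be slow.
- The auto weight-decay constant is calibrated at desk scale (see above).
- The PWM scanner is a fixed-threshold log-odds matcher, not a calibrated
  motif-match model.
- Master-regulator percentile cutoffs assume a reasonably large TF panel;
  with very few pairs, disable or lower `cutoff_quantile`.
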