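# Methods

## Model and procedure

`corisk` treats a tumor/normal expression study as evidence about gene
*modules*: sets of genes that are co-expressed, functionally coherent, and
collectively shifted in tumors. The pipeline composes five statistical
steps; this note records the exact conventions, defaults and the design
choices that were genuinely open.

### Functional similarity (Wang-style)

A term's semantics is its ancestor set with decayed contributions:
`S_A(A) = 1` and, for an ancestor `t`,
`S_A(t) = max over children c of t (w · S_A(c))` with `w = 0.8` for `is_a`
and `0.6` for `part_of`. All other ontology relation types are ignored.
Term similarity is `Σ_{t∈T_A∩T_B} (S_A(t)+S_B(t)) / (SV(A)+SV(B))`;
gene similarity is the best-match average over the two direct annotation
sets. Annotation sets are *not* expanded to ancestors — ancestry enters
only through the S-value recursion. Multiple parents take the max over
children contributions, which needs no tie-break. GAF `NOT` qualifiers are
dropped; evidence codes are not filtered (keeping all maximizes coverage;
both choices sit in the reader).

### Network construction

Both the binned trend and the edge filter use |r|, folding negative
co-expression in (configurable to signed-positive). Mean similarity is
binned against |r| in half-open 0.05 bins; empty bins carry an explicit
marker and never enter the fit. Threshold selection fits a cubic to the
bin means (bins weighted equally, as a plotted-bin-means reading implies)
and takes the knee: the populated-bin center farthest from the chord
joining the fitted curve's endpoints. The chord endpoints come from the
smoothed curve but distances are measured at the raw bin means — smoothing
a kinked trend with a low-order polynomial otherwise drags the
maximum-distance point well below the kink (observed shift: ~0.12 on a
planted knee at 0.80). A near-linear trend (max chord distance < 0.01 on
the similarity scale) raises an explicit no-knee error instead of
returning an arbitrary point; manual thresholds are always available, and
the shipped defaults are r > 0.82, sim > 0.582 (strict inequalities).
Constant-expression genes are excluded silently (their correlation is
undefined); unannotated genes are excluded with a count.

### Differential expression

Dichotomization is at the gene's own across-sample mean; values exactly
equal to the mean count as low (fixed, documented tie rule). The Bayes
factor compares independent tumor/normal high-expression rates against a
common rate, Beta(1,1) priors (configurable Beta(a,b)), computed in
log-Beta space so it is finite for every table; the all-zero table gives
exactly 0.

The randomization null fixes all four margins — class sizes are fixed by
design, high/low totals by the dichotomization — so each iteration is a
hypergeometric redraw of the tumor-high count. The null is therefore
discrete, and the tie convention decides the attained size. Measured on
2,000 Gaussian null genes (20+20 samples, α = 0.05, 10,000 iterations):
counting `random ≥ observed` rejects 1.2% of genes, counting strict
`random > observed` rejects 9.2%. Neither is close to nominal, so the
default is the standard **mid-p** convention (strict exceedances plus half
the tie mass), which attains 3.7–4.4%; both pure conventions remain
available (`comparison="geq" | "greater"`). No add-one smoothing by
default; no multiple-testing correction (a raw p < 0.05 cut, matching the
method's published form). Per-gene randomization substreams are keyed by a
CRC of the gene identifier, so results are independent of gene order.

### Markov clustering

Self-loops are set to each node's maximum incident weight (common MCL
practice), edge weight is the Pearson |r| (similarity is used only for
thresholding; unweighted is available), columns are normalized, and
expansion (matrix square) alternates with inflation (entrywise power 1.8,
prune < 1e-5, renormalize) until the max-norm change drops below 1e-8 or
200 iterations. Clusters are weakly connected components of the surviving
flow graph, which merges overlapping attractor systems and guarantees a
partition. Nodes are processed in sorted order, making the partition
independent of insertion order. Candidate modules are clusters of ≥ 3
genes (the published module table's smallest module) containing ≥ 1
DE-gene, with IDs assigned by descending size then lexical gene order.

### Module and sample risk

The Z-test reference is built from per-normal-sample module *means* (not
pooled gene-level values): x̄ and σ are then commensurate with the
tumor-side module mean. σ is the population SD (ddof = 0). The test is
two-sided — modules may be induced or repressed. A degenerate reference
(σ = 0) yields p = 1 with a warning rather than an exception.
`M_risk = n_significant / n_tumor` exactly; table-style rendering
*truncates* (floors) to 4 decimals, since the published values for 27/28
and 25/28 are truncations, not roundings.

The random-module null redraws equal-size gene sets without replacement
from a background pool and counts `random M_risk ≥ observed` (the
conservative convention; an observed M_risk of 0 carries no evidence and
returns p = 1 outright, which also guards the degenerate all-zero null).
In the pipeline the background defaults to all genes of the expression
profile (configurable to network nodes): a thresholded network built from
generated data contains almost exclusively planted-module genes, and a
background dominated by shifted genes destroys the null.

`S_risk` is the indicator mean — the fraction of cancer-risk modules for
which the sample's Z-test p is below α — the only simple form consistent
with `S_risk ∈ [0, 1]` and a 0.8 disease-call threshold; a `soft=True`
variant averages `1 − p` instead. Normal samples are scored leave-one-out
(their own value excluded from the reference) to avoid self-reference.
The ROC groups tied scores into single steps; its trapezoidal AUC equals
the Mann–Whitney statistic with the half-tie correction.

### Hypergeometric overlap

Upper-tail `P(X ≥ k)` with the population being a configurable universe
(network genes by default in the pipeline). Raw p < 0.05 flags, no
multiple-testing correction by default (a Benjamini–Hochberg pass can be
applied downstream); complex members outside the universe are excluded
from the test.

## Synthetic data generator

The generator emulates exactly the structure the method assumes: each
planted module's genes share one latent factor with loading √ρ plus
independent √(1−ρ)-scaled noise, so the expected within-module pairwise
correlation is ρ; tumor samples add δ noise-SD units to every module gene.
The ontology is one root with a dedicated subtree per planted module plus
decoy subtrees; a module gene is annotated into its own subtree with
probability `coherence` (default 0.8, so functional similarity is
informative but imperfect) and into a decoy subtree otherwise. One complex
copies each planted module exactly, plus random decoy complexes. All
output is a pure function of the seed.

Defaults are the recovery study conditions: 3 shifted modules
(size 5, ρ = 0.7, δ = 2.5) among 20 unshifted ones, 200 genes,
20 + 20 samples, unit noise SD, Gaussian throughout.

What the generator does *not* emulate: platform/batch effects, probe-level
noise, heavy-tailed or count-distributed expression, correlated noise
between modules, annotation bias toward well-studied genes. Passing tests
therefore demonstrate correctness of the machinery and recovery under the
model's own assumptions, not performance on real microarray data.

## Problem sizes used by the test and acceptance suites

Oracle suites run on exhaustively enumerable sizes (DAGs ≤ 8 terms,
contingency tables ≤ 40 samples, overlap universes ≤ 13 genes, 500 random
score sets). Calibration uses 2,000 null genes at 10,000 randomization
iterations; recovery uses the default generator conditions over 20 seeds
with 10,000 null draws per module, and the end-to-end AUC is measured on
the samples pooled across those 20 runs (800 samples), since a single
40-sample cohort estimates AUC with a standard error of ~0.02. The
pipeline smoke tests use a 60-gene, 12 + 12-sample study.

## Known limitations

- The tangency-point construction assumes a single knee; multi-phase
  trends return the most prominent one.
- MCL granularity is only statistically monotone in inflation; the suite
  allows rare violations on small random graphs.
- The Z-test treats the normal reference as exact; with few normal samples
  its tails are optimistic (a t-type correction is not applied, matching
  the published procedure).
- Cross-platform identifier harmonization, GEO parsing and enrichment
  against external services are out of scope by design.
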