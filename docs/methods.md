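# Methods

This note documents the statistical procedures implemented in `amlmo`,
their assumptions, the defaults and why, and what the synthetic-data
generator does and does not emulate.

## Study design modelled

One healthy control group (Lin-depleted bone-marrow HPSCs) and six AML
materials: three cell lines (MLP3-cl, RF12-cl, RF26-cl), two primary
AMLs (RF12-p, RF26-p), and one in-vivo passaged line (MLP3-ivp).
Transcript data are log2 intensities (features × samples); proteome
data are per-material mean SLRs (signal log2 ratios vs control) with
missing entries where a protein was not detected in a material.

## Noise model and feature filtration

The pooled log2 intensity distribution of an unfiltered array matrix is
bimodal: a low-intensity non-expressed (noise) component and an
expressed component. We fit a 1-D Gaussian mixture by EM
(`sklearn.mixture.GaussianMixture`), selecting the component count by
BIC up to `max_components` (default 3). The noise threshold is the
intensity above the lowest-mean component's mean where that component's
posterior responsibility falls below 0.5, found by bisection; with one
component nothing is classified as noise (threshold −∞). The 0.5
posterior rule is this package's choice of thresholding rule for the
mixture — it is the Bayes decision boundary between the noise and
expressed components.

Filtration keeps a feature when (a) its maximum per-group mean exceeds
the noise threshold and (b) its cross-sample variance exceeds the
`variance_quantile` quantile (default 0.25) of all feature variances.
Rule (b) removes uninformative near-constant features; we read the
"variance threshold" of the modelled analysis as retaining
*above*-threshold-variance features, since the filtered matrix feeds
clustering and differential expression, both of which need variation.
`variance_quantile = 0` disables rule (b). For very large matrices the
mixture is fitted on a deterministic 200k-value subsample; estimates of
two well-separated component means are insensitive to this.

## Differential expression

Per feature, a one-way ANOVA on the seven material groups (or a two-way
additive line × material-class model when both factors have ≥2 levels;
no interaction term, since the replicate structure is unspecified)
provides the omnibus mean squares. Pairwise comparisons use the
Tukey–Kramer studentized-range statistic
`q = |x̄_a − x̄_b| / sqrt(MSE/2 · (1/n_a + 1/n_b))` with the pooled
within-group error, valid under unequal group sizes. Features with zero
residual variance are flagged untested rather than given a p-value.

Because `scipy.stats.studentized_range.sf` integrates numerically per
point, matrix-scale sweeps evaluate it on a dense q-grid once per
(k, df) and interpolate log-p with a monotone cubic (relative error
~1e-7, checked against the exact routine); batches of ≤256 values use
the exact routine directly.

Directional calls: for each material-vs-control contrast the one-sided
p per direction is half the two-sided p when the observed sign matches
the hypothesis and one minus that half otherwise. Benjamini–Hochberg
runs separately within each direction (up and down are separate
hypothesis families) and within each contrast by default (pooling over
contrasts is available via a flag). A feature enters the up (down) set
when `q_up ≤ α` (`q_down ≤ α`); with α < 0.5 the two sets are provably
disjoint. Default α = 0.05.

Note on calibration: the Tukey–Kramer pairwise p controls the
familywise error over the k(k−1)/2 pairs of one feature, so for k > 2
its per-pair null rejection rate is deliberately below α; with k = 2 it
reduces exactly to the pooled-variance two-sample t test, where the
per-pair rate is α. Downstream BH on these p-values is therefore
conservative, never anti-conservative.

## Proteome quantification

Only proteins detected in at least four of the six materials are
analysed. Remaining missing cells (≤2 per protein) are imputed: the k
(default 5) complete proteins nearest in Euclidean distance over the
target's observed materials are averaged into a neighbour profile; an
ordinary least-squares line from that profile to the target's observed
values is evaluated at the missing material. Ties in distance break by
protein identifier, making the result independent of row order. k = 5
balances neighbourhood noise against locality at the ~1k-protein scale;
the imputation literature the design follows gives no parameter, so the
default is ours. Deregulation: fold change > 2 or < 0.5, i.e. |SLR|
strictly > 1, together with a per-cell significance criterion (p < α or
a pass flag). For printed tables that carry only mean SLRs, pass-flag
mode accepts fold change alone — the packaged 55-protein cell-line
table is internally consistent with its stated rule under this mode.
Common deregulation across materials intersects within direction
(common-up ∩, common-down ∩) and unions the two.

## Set similarity

The generalized Dice index of k sets is
`C = (k/(k−1)) · (1 − |∪S| / Σ|S|)`, which is the classic
`2|A∩B|/(|A|+|B|)` at k = 2, equals 1 iff all sets are identical and
non-empty and 0 iff pairwise disjoint. Confidence intervals use a
percentile bootstrap over the element universe (default B = 1000):
elements are resampled with replacement and the index recomputed on the
induced multisets; replicates in which a set comes out empty are
skipped, and >50% skips raise an instability error. The CI construction
is this package's choice (the modelled analysis states only "95%
confidence interval"); percentile bootstrap is distribution-free and
reproducible under a fixed seed. Measured coverage under a known
element-level overlap model is ~93–96% — the familiar mild
anti-conservatism of percentile intervals at moderate n.

## Multi-omic signature

Step (i) maps quantified proteins to transcripts via a static
protein→gene table; unmatched proteins are reported, never dropped, and
multiple proteins per gene are flagged. Step (ii) tests each mapped
gene for separation of cell-line samples from primary/in-vivo samples
with a pooled-variance two-sample t test, Bonferroni-corrected over the
mapped genes only (the modelled analysis specifies the correction but
not the test; a two-group comparison is the minimal choice). Step (iii)
requires |SLR| > log2(fold_threshold) (default 2-fold) in **every**
material; the transcript fold change is not additionally thresholded.
Step (iv) keeps a pair only when the transcript direction is the same
in all six materials and the protein direction is either equal to it
everywhere (concordant_up/_down) or opposite everywhere
(discordant_gene_up/_down). Discordant pairs are retained deliberately:
primary AMLs show negative transcript–protein correlation, and the
package provides a per-pair Spearman correlation (average ranks on
ties; undefined → NaN on constant vectors) to quantify this. Pairs with
a missing direction call in any material are excluded and logged.
Raising the fold threshold can only shrink the signature.

## Over-representation

The classic test is the exact hypergeometric upper tail
`P(X ≥ hits)` with population, annotated and drawn counts taken after
intersecting the term's genes with the background. The parent-child
variant conditions on the term's parents: the background becomes the
genes annotated to the union of the parents (intersection available by
flag; the union variant is the package default where the source is
silent), which removes inheritance-driven inflation on a DAG. A term
annotated identically to its parent is fully absorbed (p = 1).
Annotations are propagated up the ontology (true-path semantics) before
testing; orphan terms fall back to the classic test with a notice.
Catalog-wide scans BH-adjust across terms and rank by p.

## Cross-platform validation

Each dataset is z-scored per feature against its own controls
(mean/SD with ddof = 1; zero-variance features excluded with a notice),
which is exactly invariant to per-dataset affine transforms
`x → a·x + b`, a > 0 — the property that makes cross-platform
comparison possible. Replicates are averaged within material groups per
dataset, all group profiles are pooled, and UPGMA (average linkage)
clusters the columns under a standardized Euclidean metric (features
standardized to unit variance within the clustered matrix). UPGMA is
implemented directly — inter-cluster distance is the unweighted mean of
all cross-pair distances, merge heights are non-decreasing, and equal
distances break by the lexicographically smallest cluster-label pair,
so results are deterministic and column-order invariant; scipy's
average-linkage and a brute-force cophenetic check serve as independent
oracles in the tests. The validation report gives the dendrogram
(Newick), the two-cluster cut, and its adjusted Rand index against the
case/control labelling; joint clustering of pooled group means across
datasets is used (rather than per-dataset clustering), matching the
averaged-samples design. Validation proceeds on the gene intersection
when ≥50% of signature members are present in every dataset, else
aborts.

## Synthetic data

`generate_multiomic` emulates the study: 30% of transcripts are
non-expressed noise near log2 intensity 3 (SD 0.3 feature jitter),
the rest expressed near 9 (SD 1 jitter), with additive Gaussian
measurement noise (default SD 0.25) and 4 replicates per group —
defaults of 20,000 transcripts and 1,000 proteins mirror the modelled
scale. Planted directional effects of ±`effect_log2` (default 3)
create per-material truth sets; planted signature pairs (default 17,
cycling the four concordance patterns) additionally get a same-sign
doubling in the cell-line materials so they genuinely separate cell
lines from primary/in-vivo material. Protein SLRs equal the transcript
group effect (concordant) or its negation (discordant) plus noise.
Decoy pairs failing exactly one signature criterion (separation without
protein deregulation; deregulation without separation; a
direction-flipping protein) make signature recovery a two-sided test.
Missingness hits a random 20% of non-planted proteins in 1–2 of 6
materials; planted and decoy proteins stay complete so the recovery
check is not confounded with imputation error. All randomness comes
from one explicitly seeded generator; equal seeds give identical
output.

`generate_validation_datasets` derives extra "platforms" as affine
transforms (scale, offset drawn per dataset) of the base per-group mean
patterns with fresh noise (scaled so control-referenced z effects are
preserved) and fresh control samples.

Not emulated: probe-level array structure, MS spectra and peptide
inference, batch effects beyond affine distortion, and correlated
feature blocks. Passing tests therefore demonstrate correctness of the
procedures under idealised Gaussian noise, not robustness to the full
messiness of real array/MS data.

## Problem sizes and numerical choices

The test suite runs the full-scale recovery check once (20k × 28
samples, ~20 s) and otherwise uses scaled-down datasets (hundreds to
thousands of features) chosen so each check completes in seconds;
Monte-Carlo checks use enough replicates that their 2-standard-error
bands are decisive. Degenerate inputs fail loudly: zero residual
variance (untested feature), empty sets (undefined Dice), constant
vectors (undefined correlation), zero control variance (unscorable
feature), non-positive affine scales, and <2-item clustering all raise
or flag rather than return numbers.

## Known limitations

- The two-way ANOVA is additive only; interaction structure, if any, is
  folded into the residual.
- The parent-child union/intersection choice and the bootstrap CI
  construction are package decisions where the modelled analysis is
  silent; both are flagged in the API.
- Per-contrast (rather than pooled) BH is the default; with strongly
  dependent contrasts the pooled variant may be preferred.
- The printed cell-line protein table carries three conditions; type
  contracts requiring six conditions are enforced per-operation
  (detection filter, imputation), not on the container.
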