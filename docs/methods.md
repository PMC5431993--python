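# Methods

This note documents the models and procedures implemented in `sysgen`,
the defaults and why they were chosen, the numerical decisions, and
what the synthetic-data experiments do and do not demonstrate.

## Synthetic data model

`sysgen.simulate` generates every input the pipeline consumes from one
integer seed. Each component draws from its own deterministic
sub-stream (`default_rng([seed, component_code])`), so adding a
component never perturbs another's output and a fixed seed reproduces
every file byte for byte.

**Expression.** A latent-factor model: module *m* has a per-sample
standard-normal factor *e<sub>m</sub>*, and member gene *i* is
*x<sub>i</sub>* = *w<sub>i</sub> e<sub>m</sub>* +
√(1−*w<sub>i</sub>*²) ε with loading *w<sub>i</sub>* uniform on
(0.5, 0.90) and background genes pure noise; rows are standardized.
This reproduces the module/eigengene duality weighted coexpression
analysis assumes: the eigengene estimates the factor and kME estimates
the loading. Each module's first member is a planted hub with loading
pinned at the top of the range (0.95) and a 0.05 gap to the other
members — without the gap the maximally connected gene is not
identifiable at n = 200, because the top order statistics of 40 iid
uniform loadings are closer together than the sampling error of
estimated connectivity. Defaults: 1000 genes, five 40-gene modules,
200 samples.

**Traits.** BMI-like *y* = β₁ *e*₁ + β₂ age_std + ε with β₁ = 0.6,
β₂ = 0.3, σ_ε = 0.74 (so cor(*y*, *e*₁) ≈ 0.6); age uniform on
[30, 70]; obesity is the indicator of *y* above its 70th percentile
(30% prevalence — stable power for the group tests). Two additional
quantitative traits (fat-mass-like, HDL-like) are ±0.5 correlates of
the factor.

**Causal fixture.** A linear SEM generated in topological order,
x_child = Σ w x_parent + N(0, 1). The default DAG has a root R driving
A1..A4 (w = 0.8), independent co-parents Z1..Z4 → A_i (w = 0.6) that
create colliders so the constraint-based search can orient edges, and
leaves A_i → B_i (w = 0.8). R is the unique key driver by construction
(out-degree 4, three-layer downstream neighborhood of 8). The fixture
uses n = 1000 samples: at n = 200 a noisy proxy of a true separator
(e.g. a sibling of the conditioning variable) passes the α = 0.01
Fisher-z test often enough to corrupt edge orientations, whereas at
n = 1000 the population partial correlations (≈ 0.24 at the weakest
point) are rejected with overwhelming margin.

**miRNA.** Target miRNA *j* is −γ·x_target + √(1−γ²) noise with
γ = 0.5; 30 background miRNAs are pure noise. The target table holds
the 20 true pairs plus 180 decoys pairing background miRNAs with
module genes — database predictions without expression support, the
realistic false-positive mode for a sequence-based target database.

**Study collection.** k = 5 replicate datasets re-drawn from the
discovery loading structure (new factors and noise), half of each
study's samples labelled obese, and every gene carrying module
structure in that dataset shifted by −δ = −1.0 within-group SD units
in the obese group. Because the shift is applied after generating
unit-variance rows, the planted standardized mean difference is
exactly δ. An optional extra dataset permutes the gene–factor
assignment (and shifts its own scrambled module genes), destroying the
reference module for preservation testing.

**GWAS fixture.** Non-overlapping transcript spans on synthetic
chromosomes; 1–20 SNPs per gene in the body + 1 kb upstream window;
the per-gene minimum SNP p is uniform(0, 0.05) for planted genes and
uniform(0, 1) for background; consecutive SNPs within a gene are
linked at r² = 0.9 to exercise proxy clustering.

What the generator does **not** emulate: platform noise models, probe
multi-mapping, batch structure, non-Gaussian marginals, correlated LD
across genes, realistic minor-allele-frequency spectra, or any
dependence between GWAS signal and expression effect sizes. Passing
tests therefore demonstrate that the estimators recover the structures
they target under their own modelling assumptions — not performance on
real microarray data.

## Stage I

**Gene-wide p-values.** A SNP maps to a gene when its position falls
in [start − 1000, end] on the + strand, [start, end + 1000] on the −
strand (1-based inclusive); multi-gene SNPs count in every overlapping
gene. Proxy clusters are single-linkage connected components of the
r² ≥ 0.80 graph (the comparison direction is configurable; pairs
missing from the LD table count as r² = 0). The gene-wide p-value is
the minimum over singleton and cluster p-values — algebraically the
global minimum, invariant to the clustering, which is retained for
reporting. Candidate selection is inclusive (p ≤ α). Genomic-control
correction is assumed already applied upstream.

**QC.** The detection filter removes genes with detection p ≥ 0.01 in
≥ 90% of samples (both inclusive). KNN imputation (k = 10, the classic
impute-package default; no value is standard in the literature) fills
each missing cell with the mean over the k nearest gene rows by
masked Euclidean distance, falling back to the gene's row mean when no
neighbor is observed at that sample; genes ≥ 50% missing are dropped.
Sample outliers are flagged by |PC1 z| > 3 or by joining the
average-linkage dendrogram as a singleton above mean + 3 sd of merge
heights; both criteria are reported because either alone is defensible.

**Network construction.** Adjacency |cor|^β with β = 6 by default;
`pick_soft_threshold` returns the smallest power whose connectivity
distribution attains signed scale-free fit R² ≥ 0.8 (log₁₀ frequency
regressed on log₁₀ mean connectivity over 10 equal-width bins, R²
signed by −slope). TOM follows the shared-neighbor formula with
connectivity sums excluding the diagonal and TOM_ii = 1.

**Module detection.** Average-linkage clustering of 1 − TOM followed
by a two-pass cut:

1. The dendrogram is cut at each of a grid of merge-height quantiles
   (0.99 down to 0.1). Branches of ≥ `min_module_size` (30) genes are
   scored by their mean silhouette width on the *rank-normalized*
   dissimilarity — TOM dissimilarities compress into a narrow band
   near 1 at high powers, and ranks make the criterion scale-free. A
   branch is sound if its silhouette exceeds 0.2 *and* its mean
   within-branch rank is below 0.5 (a real module must be denser than
   a random gene set; without the second condition the background
   passes, because it is "separated" from the genuinely tight
   modules). The cut producing the most sound branches wins, ties
   broken by mean score, and only sound branches are kept.
2. Unassigned genes attach to the module of maximal kME when that kME
   exceeds 0.3; the rest are grey.

A single fixed cut quantile is not usable here: where the cut must
fall depends on how the merge heights distribute, which varies with
the power and the module tightness (on the default bundle a 0.99
quantile cut merges all modules with the background). The silhouette
model selection replaces the published dynamic branch-cutting
heuristics at implementable scale; the acceptance standard is
planted-module recovery (ARI ≥ 0.8), not label agreement with any
particular implementation. `deep_split` is accepted for config
compatibility and ignored.

**Eigengenes and statistics.** The module eigengene is the first
right-singular vector of the gene-standardized module submatrix,
scaled to unit variance and sign-aligned so members correlate
positively on average. Module–trait association is the partial Pearson
correlation of eigengene and trait given age (residual-on-residual),
two-sided p from t at n − 3 df, variance explained reported as the
squared partial correlation (the published "variance explained" does
not pin down the adjustment algebra; the standardized-regression
alternative is noted but not implemented). Binary traits enter as 0/1
(point-biserial). GS = |cor(gene, trait)|, kME = |cor(gene, ME)|
reported for members and non-members alike, p-values from the t
transform at n − 2 df. Hub criteria are strict inequalities (kME > 0.8
AND GS > 0.2), or the maximum intramodular connectivity with ties
broken by gene id. Enrichment is the upper-tail hypergeometric with
Bonferroni correction across tested categories.

**Causal structure.** The order-independent ("stable") PC variant:
adjacency sets are snapshotted per level so the result is invariant to
input row order; nodes and candidate conditioning sets iterate in
sorted id order. CI tests are Fisher-z partial correlations (submatrix
inversion), two-sided normal p, reject at p < α = 0.01. V-structures
are oriented from recorded separation sets (conflicts resolved
first-come in sorted order), then Meek rules 1–3 run to closure. Key
driver analysis restricts to the module subnetwork, counts only
directed edges for out-degree and for the h-layer downstream
neighborhood (conservative reading of "downstream": CPDAG-undirected
edges are never traversed), uses h = 3 by default (no published value
exists; exposed as a flag) and sample (n − 1) standard deviations in
both thresholds.

**miRNA integration.** Pearson correlation per database-predicted
pair; the default test is one-sided against r < 0 — back-calculation
of published miRNA–hub-gene p-values from their printed correlations
at n = 199 matches the one-sided, not the two-sided, value. BH
adjustment runs across exactly the database-supported pair set;
selection requires r < 0 and FDR < 0.05. The database's own prediction
p-value is carried through but never combined with the correlation p
(no combination rule is published).

## Stage II

**Preservation.** Four statistics compare the module between reference
and test data: density — mean signed intra-module correlation and mean
intra-module adjacency at the reference power; connectivity —
correlation of intramodular connectivity vectors and correlation of
the vectorized intra-module correlation matrices. The permutation null
reassigns the module label to uniform same-size gene sets of the test
network (the observed set excluded); each statistic is standardized by
its permutation mean and sd (a zero permutation sd yields +inf with a
warning), Zdensity and Zconnectivity are medians of their two
component Z scores, and Zsummary is their mean. The published
composite aggregates many more statistics whose identities are not
recoverable; this 4-statistic median-then-mean architecture mirrors it
at implementable scale and is validated by threshold behaviour
(planted preserved modules score ≥ 10, scrambled ones < 2), not by
value-matching any external implementation.

**Meta-analysis.** Per-study moderated t (below) supplies the p-values
entering Fisher's χ² = −2Σln p on 2k df, where k counts only the
studies in which the gene is measured — reconstruction of the
published hub-gene table shows the per-gene k is mandatory, not a
global constant. Effects are Hedges g: the pooled-SD standardized
difference with small-sample correction J = 1 − 3/(4(n_A+n_B−2)−1) and
variance (n_A+n_B)/(n_A n_B) + g²/(2(n_A+n_B)). Heterogeneity: Q,
I² = max(0, (Q−(k−1))/Q)·100, Q-test p from χ²(k−1). Pooling is
inverse-variance fixed-effects unless Q-p < 0.05 *or* I² > 50%, in
which case DerSimonian–Laird random effects (τ² moment estimator)
apply; 95% CI = pooled ± 1.96·SE, z = pooled/SE. Both pooling paths
reproduce `metafor::rma` to 9 decimals on a frozen cross-check. The
optional permutation p permutes group labels within each study and
applies the +1 correction, p = (1 + #{|z_b| ≥ |z_obs|})/(B+1), so zero
p-values cannot occur.

## Stage III

**Moderated statistics.** Per-gene OLS (group + covariates), residual
variances s² shrunk toward a common prior:
s̃² = (d₀s₀² + d·s²)/(d₀+d), with (d₀, s₀²) estimated by moment
matching on log s² (the difference of the log-variance ensemble's
dispersion from the χ² sampling value identifies d₀ through the
trigamma function, inverted by bracketed root finding). The moderated
t uses d₀+d df; the moderated F over a contrast matrix C is
(C′b)′[C′(X′X)⁻¹C]⁻¹(C′b)/(q·s̃²) on (q, d₀+d) df. When the ensemble
is no more dispersed than sampling alone, d₀ = ∞ and the reference
distribution degenerates to normal/χ²; scipy needs a finite df, so df
is capped at 10⁹. With fewer than 3 residual df the shrinkage is
unreliable and ordinary t-statistics are used with a warning. The
implementation reproduces Bioconductor limma's eBayes t and p to
≈ 1e-13 on a frozen cross-check fixture. Fold changes require the
caller to declare the log2 scale and return 2^(Δ mean log2).

**BH FDR** is the explicit step-up with monotonicity enforcement and
cap at 1, preserving input order; it matches the statsmodels
implementation to 1e-12.

## Pipeline

All interchange is plain TSV (diffable in tests); every output table
carries a `# config_hash=` header computed over the analysis-relevant
configuration (the output directory is excluded so identical analyses
are byte-identical regardless of destination). Config validation
aggregates all problems instead of failing fast. A MANIFEST records
completed stages; a stage failure leaves the partial MANIFEST behind.
The pipeline's causal stage caps the PC conditioning-set size at 3 to
bound the combinatorics on dense subnetworks.

## Problem sizes and runtimes

The default experiments are sized for fast iteration: 1000 genes ×
200 samples for the network (module detection ≈ 1 s), 400 genes for
preservation with 100 permutations (≈ 1 s per module/test pair), 500
genes × 5 studies for meta-analysis calibration (< 1 s), 13-node SEMs
at n = 1000 for causal recovery. The full test suite runs in well
under a minute; the acceptance script in a few seconds.

## Known limitations

- Module detection targets well-separated latent-factor modules;
  overlapping or nested modules, and signed networks, are out of scope.
- The PC implementation tests all conditioning sets exhaustively per
  level and is intended for module-scale subnetworks (tens of nodes),
  not transcriptome-scale graphs.
- Preservation Z scores for connectivity can be conservative (even
  negative) when the permutation pool is dominated by module genes,
  because mixed permuted sets inherit trivially high connectivity
  correlations; the composite remains well behaved when the module is
  a modest fraction of the network, which is the intended regime.
- The moderated-variance estimator assumes a common prior across all
  genes; no robustified or trended-prior variant is provided.
- No latent-confounder causal search (FCI) and no bootstrapped edge
  stabilities.
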