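# Methods

`crossclust` implements a cross-platform subtype-discovery methodology:
evaluate a grid of data-processing choices by consensus-clustering merged
microarray + RNA-seq data, quantify how well each choice removes platform
structure while preserving biological clusters, clean sample labels with an
iterative classifier ensemble, and extract biomarker panels that transfer
across expression and proteomics. This note records the models, the default
parameters and why they hold, the numerical conventions, and what the
synthetic cohorts do and do not establish.

## Synthetic cohorts

The generator (`crossclust.sim`) draws a latent per-gene log2 expression
level shared by all platforms and pushes it through platform-specific
observation models.

* **Latent model.** Baseline per-gene means μ_g ~ N(4, 2²) log2 units and
  effective coding-exon lengths ~ logNormal(log 1500, 0.5) bp give a
  realistic dynamic range and length spread. Biological noise is N(0, 0.5²)
  per gene and sample.
* **Subtypes.** A fraction (default 10%) of genes are markers; each marker
  belongs to one subtype and shifts that subtype's samples by a signed
  effect with mean 2.0 log2 units (SD one quarter of the mean). Classes are
  balanced within each platform; the two platforms carry disjoint sample
  sets, as in a pooled public cohort.
* **RNA-seq.** Counts are negative binomial with mean proportional to
  library size × gene length × 2^latent (library sizes uniform on
  [5·10⁵, 2·10⁶], dispersion 0.1). The stated library size is the sampling
  target; realized column sums fluctuate around it by a few percent.
* **Microarray.** The default platform effect is per-gene probe saturation:
  on the linear scale y = L·x/(x + K_g) with L = 2¹⁴ and K_g twice the
  gene's median linear expression, then log2 and N(0, 0.3²) measurement
  noise. An affine per-gene distortion and a no-effect mode are available.
  The saturation model is strong enough that raw merged data cluster purely
  by platform — the failure mode the evaluation statistics must detect.
* **Batches.** Each platform has (default) two batches with per-gene shifts
  ~ N(0, 0.2²) added on the log2 scale.
* **Outliers.** An outlier sample is a *chimera*: every gene value is
  borrowed from a random other sample of the same platform. This destroys
  the class signal while leaving each gene's marginal distribution intact,
  so the outlier lies inside the data cloud where class regions overlap and
  classifier experts genuinely disagree about it. (A within-sample
  permutation of gene labels was evaluated first and rejected: it moves the
  sample far outside the cloud on every axis, and deterministic classifiers
  then agree on a single — wrong — label with high confidence, which is not
  the low-confidence behavior an outlier filter keys on.)
* **Proteomics (optional).** A random 30% gene subset with log2 abundances
  regressed toward the latent mRNA level (slope 0.8, noise SD 0.5),
  preserving marker directions — the property the biomarker sign-consistency
  rule needs.

What passing tests on these cohorts show: the pipeline removes monotone
platform distortion, recovers planted cluster structure, flags
signal-free samples and finds truly differential genes. What they do not
show: robustness to probe-level artifacts, annotation mismatches between
platforms, unbalanced class proportions, or dropout-like zero inflation —
none of which the generator emulates.

## RNA-seq units

CPM/RPKM/FPKM follow the standard definitions; FPKM divides size-factor-
corrected counts by gene length (kb) and the geometric-mean library size
(millions), with median-of-ratios size factors rescaled to geometric mean 1.
The variance-stabilizing transform is the closed-form NB stabilizer
v(x) = 2·asinh(√(α·x/s))/ln 2 − log2(4α), affinely scaled so v(x) → log2 x
for large counts; α comes from a method-of-moments fit on normalized counts
("auto"). This replaces a dispersion-trend VST: the stabilizing intent is
identical, but genes with mean-dependent dispersion are only approximately
stabilized. voom is represented by its log-CPM component,
log2((c+0.5)/(N+1)·10⁶); the observation-level precision weights exist to
feed linear-model fits, which this pipeline never performs, so they are
omitted. Default prior count for log outputs is 0.5 (avoids −∞, common
convention). `scale_to_reference` standardizes per gene and re-expresses on
the reference gene's mean/SD; per-gene (not global) moments are used
throughout because the biomarker stage needs platform-comparable values
gene by gene.

## Cross-platform normalization

* **FSQN** maps, per gene, target values onto linearly interpolated
  empirical quantiles of the reference gene at plotting positions
  (k − 0.5)/n; ties break by stable order, so within-gene ranks are
  preserved and the gene's center and spread become those of the reference.
* **Quantile normalization** uses the same plotting-position convention;
  with a reference, columns map onto the reference's mean-quantile vector.
* **TDM** log2(x+1)-transforms the (linear/count) target, clamps values
  beyond Q3 + spread_hi·IQR and Q1 − spread_lo·IQR — the spreads taken from
  the reference's relative tail extents in IQR units — and maps the clamped
  range affinely onto [min(ref), max(ref)]. Already-logged inputs are
  un-logged first so both entry paths agree. The map is monotone and the
  output always lies inside the reference range.
* **ComBat** is the parametric empirical-Bayes location/scale adjustment
  (backed by scanpy's implementation), called without covariates; platform
  correction uses platform as the batch variable, series correction within
  a platform is the same operation earlier in the pipeline. A single batch
  is a no-op; singleton batches and zero-variance genes are rejected.

## Feature selection, clustering, statistics

Genes are ranked into 8 equal-count bins by mean expression (pooled across
platforms) and 128 genes per bin are taken by the scorer — MAD (with the
1.4826 normal-consistency constant), SVD-entropy contribution (entropy of
the squared-singular-value spectrum; a gene's score is the entropy drop when
it is removed, computed by rank-one Gram downdates), or the Laplacian score
on a heat-kernel kNN sample graph (k = 5, kernel width = mean squared kNN
distance; zero-variance genes rank last). Binning on the pooled matrix
keeps selection platform-balanced. Further scorers attach via
`register_scorer`.

Consensus clustering resamples 80% of samples 250 times (configurable),
clusters each subsample with Ward/Euclidean (or k-means), and records the
co-clustering fraction among co-sampled pairs; never-co-sampled pairs get
consensus 0 with a warning. Final labels cut an average-linkage tree on
1 − consensus; the dendrogram leaf order is kept because the randomness
statistics need a clustering-derived sample sequence. Optimal k (2–6) is a
majority vote of three indices — the largest k whose consensus-CDF area
still grows by >5%, the silhouette maximum, and the Calinski–Harabasz
maximum — with ties toward smaller k. A three-index vote keeps the decision
structure of a large multi-index vote at a fraction of the code.

The statistics: purity compares cross-platform labels against each
platform's own clustering and takes the *minimum* across platforms (the
conservative choice; pooling modes are configurable); AMI/ARI/NID/NVI are
aggregated the same way (max for the distance-like NID/NVI). Platform
entropy is the platform-composition entropy within clusters normalized to
[0, 1]; Cramér's V uses the uncorrected χ². The runs ratio and the Bartels
rank von Neumann ratio (midranks for ties; null expectation 2) are computed
within clusters along the leaf order and pooled size-weighted; clusters
that are single-platform are skipped with a warning, and if every cluster
is platform-pure the RVN defaults to 0 (maximal clumping). min(O/E) is the
smallest cluster over n/k.

## Grid ranking

The grid is the Cartesian product of the four method lists (384 cells;
the microarray entries mas5/rma both alias the already-summarized input
matrix, since probe-level processing is out of scope). Filters are strict:
purity > 0.8, min(O/E) > 0.1, and a platform-entropy screen that by default
removes whole cross-platform methods whose mean entropy is ≤ 0.1 (a
per-combination mode exists). Ranking weights four statistic groups
equally — (1) purity + AMI/ARI/NID/NVI, (2) entropy + Cramér's V, (3) runs
ratio + RVN, (4) min(O/E) — averaging within-group statistic ranks and then
the four group ranks. RVN is ranked by ascending |RVN − 2|: both clumping
(≪2) and rigid alternation (≫2) deviate from platform randomness. A
diagnostic reports the empirical |Spearman| matrix of the statistics so the
grouping can be checked on any dataset. Grid execution caches per-cell
results keyed by combination + configuration hash + seed, and records
failures/skips without stopping.

## Iterative ensemble classification

Each round runs (default) 100 iterations; an iteration bootstraps
`n_per_class` samples per class (with replacement) and trains, for every
class pair, 3 feature-selection methods (moderated-t q-values, per-gene
density-overlap OVL, |SVM weight| ranks) × 6 feature counts (2⁵…2¹⁰,
truncated to the gene count) × 3 classifiers (kNN k=5, random forest 100
trees, linear SVM C=1 — common defaults, configurable). Out-of-bootstrap
samples are predicted; an expert votes a sample into class c only when c
wins all w − 1 of its pairwise decisions (cyclic outcomes cast no vote).
With the defaults an expert round offers 100 × 3 × 3 × 6 = 5400 votes.

Vote *shares* divide by each sample's own out-of-bootstrap opportunity
count rather than the round capacity: at publication-scale cohorts the two
denominators coincide (a 100-per-class bootstrap leaves most of a
several-hundred-sample class untouched), but at package-test scale a sample
sits inside the bootstrap often, and the opportunity-normalized share is
the consistent estimator of the same quantity. Samples above the 90% share
feed their (possibly corrected) labels back for the next round's training
pool, which therefore only grows; rounds stop at the configured maximum or
when the count of confidently labeled samples changes by <1%. The final cut
judges each sample against the label it carries: an initially labeled
sample is retained only when its *own* class's final vote share exceeds
75% — label cleaning removes unconfirmed samples instead of relabeling
them, so a mislabeled sample (whose votes accrue to its true class) and a
signal-free outlier (whose votes scatter or accrue to some other class)
are both removed. Initially unlabeled samples are assigned their winning
class when its share clears the threshold. Feature selection inside an
expert uses only the bootstrap sample, preventing selection leakage into
the out-of-bag predictions.

The moderated t shrinks per-gene pooled variances toward a prior s₀² with
prior df d₀ fitted from the marginal distribution of log sample variances
by digamma/trigamma moments (a Newton trigamma inverse); the statistic uses
d₀ + d_g degrees of freedom and Benjamini–Hochberg q-values. d₀ = 0
reproduces the ordinary t exactly; d₀ = ∞ pools all variances.

OVL integrates the pointwise minimum of two locally adaptive Gaussian KDEs
(Abramson square-root bandwidths around a Silverman pilot) on a 512-point
grid spanning both samples ± 3 maximal adaptive bandwidths; zero-variance
samples fall back to a point-mass-smoothed density.

## Biomarker panels

Platforms are stacked on their common genes after per-gene scaling to the
microarray reference. For a class pair, each gene gets |log2FC| and OVL per
platform; the default score averages, over platforms, the mean of the
|log2FC|-descending and OVL-ascending ranks (rank averaging sidesteps the
unit incomparability of the two criteria; an OVL-filter-then-FC-sort mode
is provided). Only genes whose fold-change sign agrees on every platform
are eligible — a marker meant to be read out on both transcript and protein
must agree in direction. Panels hold 10 genes; a Ward k=2 clustering of the
panel-restricted, platform-z-scored matrix against the true pair labels
(ARI) validates separability.

## Problem sizes, determinism, edge cases

The test-suite and acceptance runs use the default 2000-gene cohort with
120 samples per platform for the clustering-recovery checks, a 2000-gene /
60-samples-per-platform cohort with a 40-per-class bootstrap for ensemble
cleaning (20 iterations, 2 rounds), and the default cohort with a protein
layer for biomarker panels — sizes chosen so each stage demonstrates its
statistical behavior at desk scale while the bootstrap still leaves enough
out-of-bag samples per iteration to estimate vote shares.

Every stochastic component takes an explicit seed; per-stage seeds derive
from a single entry point, and identical seeds give bit-identical outputs
(consensus matrices, cohorts, vote tallies). Degenerate inputs fail loudly
and early: zero library sizes, missing gene lengths, singleton batches,
zero-variance genes in ComBat, zero target IQR in TDM, undersized feature
bins, empty clusterings. Known limitations: the closed-form VST understates
dispersion trends; the delta-area elbow is a heuristic and is deliberately
outvoted by silhouette/Calinski–Harabasz on clean data; Laplacian-score
scale invariance holds for a fixed sample graph (the graph itself is
scale-sensitive); and the chimeric outlier model produces ambiguous — not
adversarial — outliers, so removal rates on real miscollected samples may
differ.
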