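# crossclust

Cross-platform consensus clustering for tumor-subtype discovery in combined
microarray and RNA-seq gene-expression data.

Expression subtypes of tumors (e.g. lung adenocarcinoma and squamous cell
carcinoma) are usually defined by unsupervised clustering of one profiling
platform at a time. Pooling public microarray and RNA-seq cohorts multiplies
the available samples, but raw merged data cluster by *platform*, not by
biology: counts and hybridization intensities live on different, nonlinearly
related scales. `crossclust` implements a complete methodology for doing
this integration honestly:

1. **Per-sample RNA-seq units** — CPM, RPKM, FPKM (median-of-ratios size
   factors), shifted log, a closed-form negative-binomial variance-stabilizing
   transform, and voom-style log-CPM.
2. **Cross-platform normalization** — feature-specific quantile normalization
   (FSQN), training distribution matching (TDM), whole-column quantile
   normalization, and parametric empirical-Bayes batch correction (ComBat).
3. **Binned unsupervised feature selection** — 2¹⁰ genes drawn equally from
   8 mean-expression bins, scored by MAD, SVD-entropy contribution or the
   Laplacian score.
4. **Consensus clustering** (Monti-style resampling) with a reduced
   optimal-k vote (consensus-CDF delta-area, silhouette, Calinski–Harabasz).
5. **Evaluation statistics** — cross- vs single-platform purity, AMI/ARI/
   NID/NVI, platform entropy, Cramér's V, runs ratio and the Bartels rank
   von Neumann ratio along the dendrogram leaf order, and min(O/E) for
   spurious clusters.
6. **Method-grid ranking** — all 384 combinations of
   {mas5, rma} × {cpm, fpkm, normTransform, rpkm, voom, vst} ×
   {ComBat, FSQN, quantile, TDM} × 8 feature scorers are enumerable; records
   are filtered (purity > 0.8, min(O/E) > 0.1, platform entropy > 0.1) and
   ranked by the equal-weight mean of four statistic-group ranks.
7. **Monte Carlo iterative ensemble classification** — one-against-one
   experts (3 feature-selection methods × 3 classifiers × 6 feature counts ×
   100 iterations = 5400 votes per round) with >90% vote-share feedback and
   a >75% final cut, used to clean labels and remove outliers.
8. **Cross-platform biomarker panels** — per class pair, 10 genes maximizing
   |log2 fold change| and minimizing the overlap (OVL) of locally adaptive
   kernel densities, sign-consistent across expression and proteomics.

A seeded synthetic-cohort generator (`crossclust.sim`) plants subtypes,
marker genes, gene-length-dependent negative-binomial counts, probe
saturation, batch shifts and chimeric outliers, so the whole pipeline is
testable without any external download.

## Worked example

```python
from crossclust import SimConfig, simulate_cohort, FeatureSelSpec
from crossclust import units, consensus_cluster
from crossclust.crossnorm import fsqn, merge_platforms
from crossclust.features import select_features
from crossclust.evalstats import platform_entropy
from sklearn.metrics import adjusted_rand_score

cohort = simulate_cohort(SimConfig(seed=1))          # 2000 genes, 120+120 samples
rs = units.voom_logcpm(cohort.counts_rnaseq)         # counts -> log2 CPM
ma = cohort.intensities_microarray

merged, plat = merge_platforms(ma, fsqn(rs, ma))     # FSQN onto the array scale
genes = select_features(merged, FeatureSelSpec(scorer="mad"))
res = consensus_cluster(merged.data.loc[genes], k=3, seed=2)

print(round(platform_entropy(res.labels, plat), 3))
print(round(adjusted_rand_score(cohort.true_labels.loc[res.labels.index],
                                res.labels), 3))
```

prints

```
1.0
1.0
```

— after FSQN the three clusters mix the two platforms perfectly (platform
entropy 1.0) and coincide exactly with the planted subtypes (ARI 1.0).
Skipping the `fsqn` call and clustering the raw merge instead gives platform
entropy 0.0: every cluster is platform-pure, the failure mode the method
grid is designed to detect.

A command-line interface mirrors the library
(`crossclust simulate | units | crossnorm | select | cluster | evaluate |
grid | rank | classify | biomarkers`); every run writes its parameters and
seed to a JSON log next to its outputs.

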