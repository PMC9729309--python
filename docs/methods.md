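# Methods

This note documents the models and numerical choices behind ecofinger:
what each stage assumes, which knobs matter, what the synthetic data
does and does not emulate, and where the design was genuinely open.

## Synthetic cohorts

`simulate.generate_cohort` draws counts from a negative-binomial model
(variance μ + φμ², dispersion φ = 0.3) with gene-level means drawn
log-normal (median 0.1 counts/cell, σ = 1.2 in log space) and a
log-normal per-cell library-size factor (σ = 0.3), so that the
10,000-count depth normalization is non-trivial.  The sparse baseline
matters: at a median of 0.1 counts/cell most genes have low
log-normalized means, which is what makes the interaction test's
pair-mean > 0.5 filter informative rather than vacuous.

Structure on top of the baseline:

* **Cohort design.** Six patients by default, each with three tumor
  cores (T1–T3), one border (B), one adjacent normal (N); 60 malignant
  cells per tumor region and 30 cells per non-malignant type
  (T, B-cell, TAM, CAF, TEC, hepatocyte, cholangiocyte) per region.
  The N region never contains malignant cells, which is what licenses
  its use as the CNV reference.
* **Malignant programs.** Each patient gets a private multiplicative
  program over 150 genes (log-normal factors around 2×, σ = 0.8).
  This single ingredient produces the observed ordering of
  heterogeneity levels: malignant cells of one patient correlate with
  each other (any region) more than with cells of other patients.
* **Copy-number gains.** Contiguous spans with a multiplicative
  fold-change applied to malignant cells only; the default plants 2×
  gains on the distal halves of chr1 and chr8 — 10 % of a
  10-chromosome genome — echoing the recurrent 1q/8q gains of liver
  cancer.  Genes are laid out uniformly on equally sized chromosomes.
* **Planted ligand–receptor pairs.** A pair elevates its
  tumor-compartment gene in malignant cells and its partner-compartment
  gene in one non-malignant type, by a 2× effect, in a configurable
  patient subset.  `partner_patients` decouples the two sides; passing
  an empty tuple leaves the partner gene at baseline, which is how
  patient-specific *tumor-driven* fingerprints are modeled for the
  switching experiment (any cell-type-specific partner elevation makes
  a pair detectable from the TME side alone).
* **Bulk cohorts.** Log2-normal expression (per-gene baseline
  N(7, 1), unit noise); each cluster over-expresses its own pair
  program by 2×.  Polarization — cluster 1 and cluster 2 each having
  enriched pairs — is essential: with a one-sided program the binary
  occurrence vectors are nearly uncorrelated within clusters and
  correlation-distance clustering has no signal.  Survival is
  exponential with per-cluster hazards (default ratio 3) and
  independent uniform censoring whose upper bound is solved
  numerically so the realized censoring fraction matches the
  configured rate.
* **Spatial samples.** Each gene's spot density is a mixture
  `overlap·shared + (1−overlap)·own`, where the shared component is a
  set of Gaussian blobs over the field and the own components are
  blobs clipped into the left/right half-fields.  At overlap 0 the
  supports are exactly disjoint; at 1 the densities coincide, so the
  Bhattacharyya coefficient sweeps 0 → 1 monotonically in the
  parameter.

What the generator does **not** emulate: ambient RNA, doublets, batch
effects, spliced/unspliced layers, cell-cycle structure, spatial
segmentation noise.  Passing tests therefore demonstrate correctness
of the statistical machinery under a clean overdispersed-count model,
not robustness to every real-data artifact.

## CNV inference and malignant calling

Genes are first restricted to those with mean raw counts ≥ 0.1 per
cell (the droplet-data convention of expression-based CNV tools; the
cutoff is exposed).  Expression is centered on the reference-cell mean
per gene, averaged over sliding windows of `window_genes` genomically
adjacent genes (step 1, per chromosome; a short chromosome collapses
to one window), re-centered on the per-window reference mean, and
clipped at ±3 reference SDs.  The window default is 100 genes, the
cited convention for real transcriptomes; analyses of the synthetic
2000-gene genome use 50 so each chromosome spans many windows.

Calling works on two statistics: the aberration score (mean squared
window deviation, reported as `cnv_score`) and the correlation of each
cell's profile with the centroid of the top-decile cells.  The
correlation is computed at *gene* resolution: sliding windows are
strongly autocorrelated (adjacent windows share all but one gene), so
a window-level correlation has roughly n_genes/window effective
degrees of freedom and measured ~2.4 SD of separation between planted
malignant and non-malignant cells, while the gene-level correlation
reaches ~4 SD under identical conditions.  Cells are partitioned by
exact 1-D two-means on the correlation (optimal sorted split —
deterministic and invariant to cell order), the centroid is refined
from the called group, and the split repeated twice.  An early design
clustered the (score, correlation) plane with seeded k-means; the
score's weak separation (~0.8 SD, inflated by cell-type programs and
depth effects) dragged accuracy below what the correlation alone
achieves, so the score is retained as a reported feature and for
seeding the initial centroid only.

Acceptance gate: the high cluster is labeled malignant only when its
mean centroid correlation exceeds 3× the reference cells' correlation
spread.  Under a no-CNV null the top-decile centroid is noise and
every cell's correlation with it is small, so the gate correctly
yields zero calls; with a 10 %-genome 2× gain the malignant cluster
sits far above it.  Reference cells are forced non-malignant
regardless.  The decision boundary between malignant and non-malignant
is not uniquely determined by the underlying method (published
analyses corroborate calls with marker expression); this rule is one
explicit, testable formalization.

## Cell typing

Leiden community detection on a k = 20 nearest-neighbor graph over 20
principal components of the non-malignant cells; each cluster receives
the arg-max mean marker-signature score, with marker genes missing
from the matrix counted as zeros (so absent markers dilute, not
crash).  T-labeled clusters are kept only if ≥ 80 % of their cells
have CD3D+CD3E+CD3G > 0 (strict less-than removal, so a cluster at
exactly 80 % stays).

## Heterogeneity

Variable genes are ranked by the variance of expression standardized
against a mean–variance trend, with standardized values clipped at
√n.  The trend is a degree-2 polynomial fit in log10 mean / log10
variance space — a deliberately simple smoother filling the role a
loess fit plays in the dominant single-cell convention; for ranking
purposes the two agree on all but trend-boundary genes.  Pairwise cell
correlations are plain Pearson over the variable-gene vectors, grouped
into intraregion / interregion / intertumor by the (patient, region)
labels; regions with fewer than two malignant cells are reported as
not detectable rather than silently dropped.

Region dendrograms use distance 1 − r between per-sample mean
profiles and Ward agglomeration on squared dissimilarities (scipy's
`ward`, which matches R's `hclust(method="ward.D2")` given the same
distances).  Ward formally assumes Euclidean input; correlation
distance is not Euclidean in general, so the tree is a heuristic — the
same heuristic the field uses — and is documented as such.  Samples
are sorted lexicographically before linkage so the tree does not
depend on input order.

Pseudo-bulk is the arithmetic mean of normalized log expression; the
cytotoxic/exhaustion ratio uses ε = 1e-8 in the denominator to keep
sparse toy data finite.

## Ligand–receptor permutation test

Statistic: ½(mean ligand in source type + mean receptor in target
type), computed only when each gene is expressed in ≥ 10 % of its
type's cells and both types have ≥ 10 cells (all three thresholds
exposed).  Null: the cell-type label vector is shuffled; sampled mode
uses the add-one estimator p = (1 + #{null ≥ obs})/(1 + N) with
N = 1000 by default, so min p = 1/(N+1) and ties count conservatively.
An exact mode enumerates all distinct label arrangements (capped at
2·10⁵) and returns #{null ≥ obs}/N_total with the observed labeling
included; the observed statistic is recomputed along the same
floating-point path as the null so that exact ties compare as ties.
Multi-subunit complexes are out of the data model: single-gene ligands
and receptors only.

Filters are strict inequalities (p < 0.01, mean > 0.5, both on the
log-normalized scale — the threshold scale is implied rather than
stated by the convention this follows, and is applied on the
normalized data).  The ubiquity rule drops a (pair, direction,
partner) key significant in every case of the case universe.

The switching experiment samples derangements (rejection sampling) of
the malignant compartments across cases, so no chimera pairs a tumor
with its own TME.  One derangement yields one chimera set; each
chimera is scored against the original key set of the case that kept
its compartment — the TME owner for `switch_tumor`, the tumor owner
for `switch_tme` — with matched proportion |chimera ∩ original| /
|original| (the original case's key set, not the union, is the
denominator).  Modes are compared by Welch's t (two-sided reported,
plus the one-sided "tumor decays faster" p).

Subsampling keeps all non-malignant cells, subsamples the malignant
compartment to each requested count, reruns test + filters, and
scores the matched fraction against the full-data reference keys.

## Stratification

Single-cell occurrence maps keep keys present in 3–10 cases
(inclusive bounds — the exclusion wording is "fewer than three" /
"more than ten").  Bulk occurrence uses the strict median rule: a pair
occurs in a sample iff its ligand+receptor mean strictly exceeds the
cohort median of that pair's scores, so ties are absent, occurrence is
at most 50 %, and the rule is deterministic.  The rule is invariant to
monotone common-across-samples transformations of expression only
when ligand and receptor are on a common scale.  Patient clustering is
ward.D2 on 1 − r over occurrence vectors, with a Jaccard fallback for
constant vectors (correlation undefined); k = 2 primary, k = 3
secondary.  Cluster identity is anchored to survival — cluster 1 is
the cluster with the shorter mean observed time — so cross-cohort
comparisons are well defined without matching dendrogram layouts.

The log-rank statistic is the textbook observed-minus-expected form
with hypergeometric variance, inverted on k−1 dimensions via
pseudo-inverse; the trend variant uses ordered group scores s:
z = sᵀ(O−E)/√(sᵀVs).  lifelines serves as an independent cross-check
in the test suite, not as the implementation, because the trend
variant is needed and the small-table oracle property is asserted
against the definition.

## Colocalization

Tiles are half-open squares anchored at the field's minimum
coordinate; partial edge tiles are kept.  This anchoring convention
(and copy-weighting of spots, with an unweighted flag) must be fixed
for bit-exact tests; nothing in the underlying definition prefers one
corner.  "Filled tile" defaults to ≥ 1 copy of *either* pair gene,
with a both-genes variant behind a flag — the either-gene reading
makes the shuffle null strictly conservative for concentration.  The
shuffle permutes per-cell gene payloads with coordinates fixed, and
each of the (default 10) shuffles provides one denominator for an
observed/null ratio.  Expression grouping uses cohort tertiles per
gene (high = all four fingerprint genes above the upper tertile,
low = all four below the lower), with the per-sample summary being
mean copies per cell; the grouping degenerates to all-others when a
gene is constant.

## Surrogate signatures

Wilcoxon rank-sum per gene (exact for small groups via scipy),
Benjamini–Hochberg adjustment, log fold-change defined as
log(mean expm1 + 1) difference of group means — the common single-cell
convention; the averaging scope ("log of group-mean ratio" rather
than per-cell mean of logs) was an open choice and is fixed here.
Surrogate sets use strict thresholds (> 1, < −1, adj. p < 0.05) and
are disjoint by construction.  The fingerprint score is the geometric
mean of the four genes with an ε = 1e-8 pseudocount.

## Problem sizes and tolerances in the test suite

The suite runs entirely on synthetic data at the study-condition
defaults where a claim depends on them (malignant-call accuracy,
planted-pair sensitivity/FPR, switching asymmetry with 20 shuffles and
1000 permutations, 200-replicate survival power, 100-simulation
heterogeneity ordering) and on deliberately small fixtures everywhere
else (3-patient cohorts, 8-cell enumeration toys, ≤ 8-sample log-rank
tables).  Statistical assertions state the rates they check (e.g.
null calibration of the permutation p within [0.03, 0.07] over 1000
pairs); identities (BC bounds, stability = 1, r = ±1) are asserted
exactly or at 1e-9–1e-12 depending on accumulation length.
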