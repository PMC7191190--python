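# Methods

## The measurement model

Array methylation is summarised per CpG as β ∈ [0, 1], the fraction of
methylated alleles in the bulk sample. For a tumor sample *s* and a
promoter CpG *i* that is specifically unmethylated in immune cell type
*t*, the bulk signal is a purity-weighted mixture

    β_si ≈ (1 − f_st) · β_i^tumor + f_st · β_i^immune-low,

where f_st is the fraction of type-*t* cells in the sample. Since
β_i^tumor is high (the CpG is selected to be hypermethylated in tumor
and stromal cells) and β_i^immune-low is near zero, bulk β decreases
monotonically in infiltration. All downstream machinery — signature
selection, clustering, scores — rests on this mixture identity.

## Signature selection

Inputs: two gene → cell-type signatures, a probe annotation (gene,
distance to TSS, platform flags), and a reference β matrix of immune
cell types plus non-immune samples (stroma, tumor lines).

1. *Signature merge.* Union of both gene lists; genes assigned to
   different cell types by the two sources are removed.
2. *Promoter mapping.* Candidate CpGs have |distance to TSS| strictly
   below 1500 bp and are present on both the 450K and EPIC platforms
   (so signatures transfer across array generations). The annotation
   supplies the distance precomputed; no array manifest parsing.
3. *Differential methylation across immune types.* β is dichotomized at
   0.3 (β < 0.3 unmethylated, β ≥ 0.3 methylated; missing propagates).
   Per CpG, the (cell types × {unmethylated, methylated}) count table is
   tested with a two-sided exact test of homogeneity (below), and
   Benjamini–Hochberg FDR < 0.01 across all candidates gates survival.
   CpGs missing in > 20 % of reference samples are excluded and logged.
4. *Stromal hypermethylation.* A CpG passes if the fraction of
   non-immune samples with β strictly above 0.7 strictly exceeds 0.98
   (melanoma mode) or 0.90 (pan-cancer mode, where heterogeneous tumor
   cell lines require a laxer quantile). All boundary comparisons in the
   package are strict; the relaxed mode is a superset by construction.
5. *One CpG per gene.* Smallest exact-test p; ties broken by larger
   reference β range, then lexicographically smallest probe ID — fully
   deterministic.

### The r × 2 exact test

With two outcome columns and fixed margins, a table is determined by its
first-column vector a, with conditional probability
P(a) = Π_i C(n_i, a_i) / C(N, c1). The two-sided p-value sums P over all
tables no more probable than the observed one (the Freeman–Halton
construction). The reference set is enumerated exactly — vectorised by
dynamic programming over rows — whenever it holds at most 200 000
tables (the count itself is obtained by DP first); the default
reference panel (7 × 6 samples) yields about 10³ tables per CpG, so
enumeration is essentially free and identical count tables share one
evaluation. Larger reference sets fall back to a seeded Monte-Carlo
estimate over margin-preserving Patefield draws (10⁵ by default),
flagged `monte-carlo` in the result. Tables are compared in log space
with 1e-9 slack so float rounding never drops a tied table. The
enumeration cap on the *number of tables* (rather than on the grand
total) keeps realistically sized reference panels on the exact path.

## Consensus clustering and centroids

The cohort is clustered over the selected CpGs with Monti-style
consensus: 1000 iterations, each drawing 80 % of samples without
replacement, Ward-linkage hierarchical clustering on Euclidean distance
cut at k; the consensus matrix is the fraction of co-sampled iterations
in which a pair co-clusters. Final labels come from average-linkage
clustering of 1 − consensus. Stray missing β are median-imputed per CpG
for the distance computation only. Clusters are renumbered by ascending
mean β over the clustering CpGs, so cluster 1 is always the
least-methylated (immune-rich) group and survival models can use it as
the fixed reference level.

Centroids: per-cluster median β over the immune CpGs whose values
differ across clusters (Kruskal–Wallis, BH-FDR < 1e-4 across the set;
constant CpGs get p = 1). Classification computes Kendall τ-b (ties are
expected among medians) between a sample and each centroid over
pairwise-complete CpGs, requiring at least 10 informative CpGs; the
sample joins the argmax centroid if max τ ≥ 0.3 (the threshold is
inclusive), otherwise it is unclassified with a reason code. Exact τ
ties go to the lowest cluster index with a warning.

## Scores, dichotomization, PTEN

Methylation score = median β per (sample, cell type) over the type's
CpGs; expression score = median (optionally per-gene median-centered)
expression over the type's genes. Medians of even counts are midpoints
of the central order statistics. Cell types with no CpG present yield a
missing, logged column rather than an error, matching screens where no
CpG survives filtering for a cohort. Scores strictly above β = 0.7 are
"hypermethylated". Pan-cancer analyses pass cohort-specific pair sets
through the identical scoring path.

PTEN: promoter and DHS CpG sets come from an annotation table
(`is_dhs` column); DHS processing itself is out of scope. A sample is
promoter-hypermethylated iff strictly more than 10 % of its non-missing
DHS CpGs exceed β = 0.7 *and* the median over all promoter CpGs strictly
exceeds 0.5; fewer than 5 informative DHS CpGs gives an undetermined
call. Alteration events OR hypermethylation, nonsynonymous mutation and
copy-number loss/deletion (consumed as categorical calls); missing
modalities count as event-free and mark the sample incomplete. The
machinery takes any gene's CpG sets, but thresholds are validated for
PTEN only.

## Statistics

- Δβ contrasts: per cell type, Kruskal–Wallis across clusters and Dunn
  pairwise z-tests on joint ranks with tie correction,
  z = (R̄_a − R̄_b) / √[(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/n_a + 1/n_b)],
  two-sided normal p; |Δβ| is the difference of cluster median scores;
  BH-FDR across cell types separately within each cluster pair (the
  comparisons answer different questions, so correction is per
  comparison). Clusters under 3 samples are excluded with a warning.
- Categorical associations: Fisher's exact test for 2×2; Pearson χ²
  without continuity correction otherwise, replaced by a seeded
  Monte-Carlo exact p (margin-preserving tables, χ² statistic) when any
  expected count is below 5. Batched annotations get BH-FDR.
- Survival: Cox proportional hazards via lifelines (Efron tie
  handling), Wald 95 % CIs and p-values; endpoints DMFS/DSS/OS; the
  reference level is cluster 1 / not-hypermethylated. A group level
  with zero events is reported as non-estimable (NaN HR) instead of
  letting the monotone likelihood diverge. The per-cell-type screen on
  dichotomized scores applies BH across cell types (significance at
  adjusted p < 0.1) and annotates HR size (large: HR ≥ 1.5 or ≤ 0.66).
  Kaplan–Meier curves are truncated at 10 years for display only; the
  log-rank test uses all follow-up.

## The synthetic-data generator

The generator emulates the data layers the analysis consumes, with
defaults chosen as the study conditions of the bundled tests.

Reference panel: K = 7 immune cell types (the canonical
peripheral-blood panel: CD4/CD8 T, B, NK cells, monocytes, neutrophils,
eosinophils) × 6 replicates, 10 stromal samples, 10 tumor lines. Each
type carries 5 marker CpGs with per-CpG archetypes — unmethylated in
the own type (U[0.05, 0.20]), methylated in other immune types
(U[0.78, 0.92]), strongly methylated in non-immune samples
(U[0.82, 0.95]) — plus 2000 background CpGs methylated everywhere and
20 confounder CpGs (immune-differential but stromal-unmethylated) that
exist to exercise the stromal filter. Observed β is Beta-distributed
with mean = archetype and concentration 100 (sd ≈ 0.03 at β = 0.85),
keeping values in [0, 1] without clipping. Background probes are split
across the exclusion routes of the promoter mapping (promoter/shared,
too far, single-platform, off-signature), so every funnel step filters
something. Two overlapping signatures are emitted with 3 planted
conflicts; optional multi-CpG genes exercise the best-CpG-per-gene
choice.

Tumor cohort: 150 samples in three strata (equal proportions) with mean
infiltrated fractions 0.45 / 0.20 / 0.05 (immune-rich → immune-poor).
Each stratum × cell type gets its own mean m_ct = m_c · w_ct, with
w drawn once per study from U[0.6, 1.8] (stratum 1), U[0.3, 1.7]
(stratum 2) and U[0.2, 1.8] (stratum 3): the strata therefore differ in
composition, not just level, which is what makes rank-correlation
centroid classification informative, and the immune-rich stratum
infiltrates every type at least moderately so each type's score retains
a wide dynamic range. Per-sample fractions are Beta-distributed around
m_ct (concentration 80). Marker β follows the mixture identity above;
expression of each signature gene is linear in its promoter CpG's β
(intercept 8, slope −4, Gaussian noise sd 0.5 — the analysis only needs
the negative link). Survival is exponential with baseline hazard
0.15/year and per-stratum hazard ratios (1.0, 2.1, 2.3), censored by an
independent Uniform(0, u) time with u solved numerically for 30 %
expected censoring. PTEN lesions are planted at per-stratum rates
(0.10, 0.30, 0.60) with the mechanism drawn uniformly among
hypermethylation, mutation and copy-number loss, plus a 30 % chance of
loss co-occurring with hypermethylation; hypermethylated samples get
promoter archetypes U[0.72, 0.92] against U[0.15, 0.40] otherwise.
Clinical covariates (age, sex, metastasis type, MITF status, TIL
category) are drawn with stratum-dependent category probabilities so
categorical associations have signal.

Determinism: all randomness flows through `numpy.random.default_rng`
(PCG64), seeded per stage as `default_rng([seed, stage])`; identical
seeds give bitwise-identical outputs across runs and platforms, and the
pipeline driver's TSV artifacts are byte-identical across reruns.

What the generator does *not* emulate: genomic coordinates and probe
cross-reactivity, batch/normalization effects, correlated infiltration
between cell types beyond the stratum structure, non-exponential
hazards, and measurement error in mutation/copy-number calls. Passing
tests therefore demonstrate correctness of the algorithms under the
stated mixture model, not performance on real cohorts.

## Expected behaviour at the default conditions

At the defaults, selection recovers all 35 planted markers with no
background CpG, consensus clustering reproduces the planted partition
exactly (ARI 1.0), and centroid classification of a freshly drawn
cohort is typically 95–100 % accurate (occasional profile draws whose
strata happen to be compositionally similar can dip to ≈ 0.9; the
uniform-noise unclassified rate stays above 95 % throughout). Problem
sizes used by the test suite and the acceptance script — 150-sample
cohorts, 300 samples for PTEN/event-rate and survival recovery, 100
replicates for Cox coverage, 200 noise profiles — were chosen so the
whole suite completes in well under a minute of compute while leaving
the Monte-Carlo margins comfortable.

## Design choices where the design was open

- Consensus clustering (algorithm unspecified upstream): Monti
  resampling with Ward base clusterer and average-linkage consensus
  cut; every knob (fraction, iterations, linkage, seed) is in
  `ConsensusSettings`.
- Contingency layout of the selection test: one r × 2 table across all
  reference types rather than per-type one-vs-rest — a single
  homogeneity test matches the "significantly different proportions
  among reference cells" reading and avoids K extra multiplicity
  layers.
- Non-immune cells and tumor lines are pooled, unweighted, in the
  stromal filter.
- "Most significant CpG" ranks by raw p (BH-adjusted values are
  monotone in p, so the ranking is identical; raw p breaks ties less
  coarsely).
- FDR procedure: Benjamini–Hochberg everywhere, recorded in reports.
- The τ ≥ 0.3 assignment threshold is inclusive; unclassified samples
  are kept in outputs (with reasons) and left to the caller to exclude
  from survival analyses.

## Known limitations

- The exact test's Monte-Carlo fallback has resolution 1/(draws+1);
  at the default FDR < 0.01 gate this is ample, but extremely small
  p-values from huge reference panels are truncated.
- Consensus clustering is O(iterations × n²) in memory-light
  accumulation but recomputes a linkage per iteration; cohorts beyond
  a few thousand samples need fewer iterations or a coarser base
  clusterer.
- `lifelines` emits convergence warnings on degenerate designs (e.g.
  perfectly separated dummy covariates); the wrapper converts outright
  failures into non-estimable flags but does not silence warnings.
- The PTEN caller trusts the provided promoter/DHS CpG sets; choosing
  them for genes other than PTEN is the caller's responsibility.
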