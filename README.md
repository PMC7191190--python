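# immunometh

DNA methylation-based profiling of the tumor immune microenvironment.

Bulk tumor methylomes (Illumina 450K/EPIC β-values, 0 = unmethylated to
1 = fully methylated) are mixtures of tumor cells and infiltrating
immune cells. Because promoter methylation is strongly lineage-specific,
a promoter CpG that is unmethylated only in one immune cell type acts as
a sensor for that type's presence: the more the type infiltrates a
tumor, the lower the tumor's bulk β at that CpG. `immunometh` turns this
idea into a reusable pipeline for epigenomics researchers:

1. **Signature selection** — from two gene → immune-cell-type
   signatures and reference methylomes (immune types, stromal cells,
   tumor cell lines), derive cell type-specific gene–CpG pairs:
   promoter CpGs (|d(TSS)| < 1500 bp, shared by both array platforms)
   whose methylation bins (β < 0.3 vs β ≥ 0.3) differ across reference
   immune types (r×2 exact test, BH-FDR < 0.01), that are
   hypermethylated in > 98 % of non-immune samples (β > 0.7; > 90 % in
   pan-cancer mode), reduced to the most significant CpG per gene.
2. **Cohort clustering** — Monti-style consensus clustering (resampled
   Ward hierarchical clustering) of tumors over the selected CpGs;
   clusters are numbered by ascending immune-CpG methylation, so
   cluster 1 is immune-rich and cluster k immune-poor.
3. **Centroid classification** — per-cluster median-β centroids over
   CpGs that separate the clusters (Kruskal–Wallis, BH-FDR < 1e-4);
   a new sample joins the centroid with the highest Kendall τ-b, or is
   *unclassified* if no τ reaches 0.3.
4. **Scoring** — per-sample, per-cell-type methylation score = median β
   over the type's CpGs (expression scores analogously, optionally
   median-centered); scores with β > 0.7 are *hypermethylated*.
5. **PTEN events** — promoter hypermethylation call (> 10 % of DHS
   promoter CpGs with β > 0.7 *and* promoter median β > 0.5), OR-ed
   with mutation and copy-number loss into alteration events.
6. **Statistics** — Δβ cluster contrasts (Kruskal–Wallis + Dunn post
   hoc, per-comparison BH-FDR), categorical associations
   (Fisher/χ²/Monte-Carlo), Cox proportional-hazards models (Efron
   ties, Wald 95 % CIs) and Kaplan–Meier log-rank tests.

A seeded synthetic-data generator (`immunometh.simulate`) reproduces the
statistical structure this analysis assumes — reference archetypes,
purity-weighted tumor mixtures with three infiltration strata, promoter-
driven expression, stratum-dependent hazards, PTEN lesions — so the
whole pipeline runs and is testable without any external cohort.

## Worked example

```python
import immunometh as im

config = im.SimulationConfig(seed=1)
panel = im.generate_reference_panel(config)
pairs, report = im.run_selection(
    panel.beta, panel.sample_types, panel.signature_a, panel.signature_b,
    panel.annotation, im.SelectionParams.for_mode("melanoma", seed=1),
)
cohort = im.generate_tumor_cohort(config, panel)
consensus = im.consensus_cluster(
    cohort.beta.loc[pairs["probe_id"]], k=3,
    settings=im.ConsensusSettings(seed=1),
)
fit = im.fit_survival(cohort.clinical, consensus.labels, endpoint="DSS")
```

Running `python examples/02_select_signature_cpgs.py` prints

```
selection funnel:
  n_genes_combined: 56
  n_candidate_cpgs: 555
  n_after_fisher: 55
  n_after_nonimmune_filter: 35
  n_pairs: 35
planted markers recovered: 35/35
```

— of 555 candidate promoter CpGs, 55 are differentially methylated
across the reference immune types, 35 survive the stromal
hypermethylation filter (exactly the planted markers; the 20 planted
confounders, differential in immune cells but unmethylated in stroma,
are removed here), and one CpG per gene remains.
`python examples/04_scores_and_survival.py` then prints

```
DSS group[2]: HR 2.50 (95% CI 1.42-4.42, p = 0.0016)
DSS group[3]: HR 2.73 (95% CI 1.58-4.69, p = 0.00029)
log-rank across clusters: p = 5.89e-04
```

— the intermediate and immune-poor clusters carry roughly 2.5-fold the
disease-specific-survival hazard of the immune-rich cluster 1,
recovering the planted per-stratum hazard ratios (2.1 and 2.3) within
confidence limits. The remaining examples cover simulation, centroid
classification of an external cohort, and PTEN alteration events.

A thin CLI mirrors the library:
`immunometh simulate|select|cluster|centroids|classify|score|pten-call|stats|run`
(see `immunometh --help`); `immunometh run --seed 1 --outdir out/` runs
every stage on a simulated study and writes TSV/JSON artifacts plus a
manifest. Reruns with the same seed are byte-identical.

## Layout

- `src/immunometh/` — the library (`simulate`, `selection`, `exact`,
  `clustering`, `scoring`, `pten`, `stats`, `readwrite`, `pipeline`,
  `cli`).
- `examples/` — one short narrative script per capability.
- `docs/methods.md` — models, parameters, numerical choices,
  limitations.
- `tests/` — pytest suite with independent brute-force oracles.
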