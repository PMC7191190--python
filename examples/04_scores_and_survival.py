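"""Per-cell-type methylation scores, Δβ contrasts, and survival models.

A sample's methylation score per cell type is the median β over that
type's signature CpGs — low score means the type is inferred present.
Cluster contrasts use Kruskal-Wallis with Dunn post hoc (BH-FDR across
cell types within each cluster pair); survival uses Cox regression with
cluster 1 (immune-rich) as reference and Kaplan-Meier log-rank.
"""

import immunometh as im

config = im.SimulationConfig(seed=1)
panel = im.generate_reference_panel(config)
pairs, _ = im.run_selection(
    panel.beta, panel.sample_types, panel.signature_a, panel.signature_b,
    panel.annotation, im.SelectionParams(seed=1),
)
cohort = im.generate_tumor_cohort(config, panel)
labels = cohort.truth.sample_cluster_labels

scores = im.methylation_score(cohort.beta, pairs)
contrasts = im.delta_beta_contrasts(scores, labels)
extreme = contrasts[(contrasts["cluster_a"] == 1) & (contrasts["cluster_b"] == 3)]
top = extreme.nlargest(2, "abs_delta_beta")
print("largest cluster 1 vs 3 score differences:")
for row in top.itertuples(index=False):
    print(f"  {row.cell_type}: |Δβ| = {row.abs_delta_beta:.2f}, "
          f"Dunn FDR = {row.dunn_fdr:.2e}")

fit = im.fit_survival(cohort.clinical, labels, endpoint="DSS")
for row in fit.itertuples(index=False):
    print(f"DSS {row.term}: HR {row.hr:.2f} "
          f"(95% CI {row.ci_low:.2f}-{row.ci_high:.2f}, p = {row.p:.3g})")
# Hazard ratios near the planted 2.1 / 2.3 confirm the model recovers
# the per-stratum hazards.

km = im.km_logrank(cohort.clinical, labels)
print(f"log-rank across clusters: p = {km.logrank_p:.2e}")
screen = im.cox_screen(im.dichotomize_score(scores), cohort.clinical, endpoint="DSS")
print(f"per-cell-type screen: {int(screen['significant'].sum())} of "
      f"{len(screen)} cell types significant at BH-adjusted p < 0.1")
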