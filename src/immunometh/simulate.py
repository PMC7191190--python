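"""Seeded simulator for methylation-array immune profiling studies.

Emulates the data layers the analysis pipeline consumes:

* a *reference panel*: methylomes of K immune cell types in which each
  type carries a handful of promoter CpGs that are unmethylated in that
  type only, next to uniformly hypermethylated non-immune stromal
  samples and tumor cell lines, and a large body of background CpGs;
* a *tumor cohort*: purity-weighted mixtures of a tumor-line methylome
  and the immune archetypes, with three planted infiltration strata
  (immune-high / intermediate / immune-low clusters), matched gene
  expression anti-correlated with promoter methylation, exponential
  survival with per-cluster hazards, and planted PTEN lesions.

All β-values are drawn from Beta distributions parameterised by
(mean = archetype, concentration), which keeps them inside [0, 1]
without clipping.  Randomness comes exclusively from
``numpy.random.default_rng`` (PCG64) seeded per stage as
``default_rng([seed, stage])``, so identical seeds give bitwise
identical outputs across runs and platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "ReferencePanel",
    "TumorCohort",
    "generate_reference_panel",
    "generate_tumor_cohort",
    "simulate_two_group_survival",
    "mixture_mean_beta",
    "write_simulation",
]

# Reinius-style peripheral-blood panel used for the default 7 cell types.
DEFAULT_CELL_TYPES = (
    "CD4 T cells",
    "CD8 T cells",
    "B cells",
    "NK cells",
    "Monocytes",
    "Neutrophils",
    "Eosinophils",
)

NON_IMMUNE = "non_immune"
TUMOR_LINE = "tumor_line"


@dataclass
class SimulationConfig:
    """Parameters of the generative model (defaults = study conditions)."""

    seed: int = 0
    n_celltypes: int = 7
    n_marker_cpgs_per_type: int = 5
    n_background_cpgs: int = 2000
    n_ref_samples_per_type: int = 6
    n_nonimmune_samples: int = 10
    n_tumor_lines: int = 10
    cohort_size: int = 150
    cluster_proportions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    # mean infiltrated fraction per stratum, high -> low (immune-rich
    # cluster 1 down to immune-poor cluster 3)
    infiltration_means: tuple[float, float, float] = (0.45, 0.20, 0.05)
    beta_noise_concentration: float = 100.0
    infiltration_concentration: float = 80.0
    hazard_ratios: tuple[float, float, float] = (1.0, 2.1, 2.3)
    pten_event_rates: tuple[float, float, float] = (0.10, 0.30, 0.60)
    expression_slope: float = -4.0
    expression_intercept: float = 8.0
    expression_noise_sd: float = 0.5
    baseline_hazard: float = 0.15  # events / year in cluster 1
    censoring_fraction: float = 0.30
    n_multi_cpg_genes: int = 0  # genes emitted with 3 promoter CpGs each
    n_cpgs_per_multi_gene: int = 3
    n_confounder_cpgs: int = 20  # immune-differential but unmethylated in stroma
    n_conflict_genes: int = 3  # genes typed differently in the two signatures
    n_pten_promoter_cpgs: int = 20
    n_pten_dhs_cpgs: int = 12

    def validate(self) -> None:
        counts = {
            "n_celltypes": self.n_celltypes,
            "n_marker_cpgs_per_type": self.n_marker_cpgs_per_type,
            "n_ref_samples_per_type": self.n_ref_samples_per_type,
            "n_nonimmune_samples": self.n_nonimmune_samples,
            "n_tumor_lines": self.n_tumor_lines,
            "cohort_size": self.cohort_size,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.beta_noise_concentration <= 0:
            raise ValueError("beta_noise_concentration must be > 0")
        if self.infiltration_concentration <= 0:
            raise ValueError("infiltration_concentration must be > 0")
        if abs(sum(self.cluster_proportions) - 1.0) > 1e-9:
            raise ValueError("cluster_proportions must sum to 1")
        for f in self.infiltration_means:
            if not 0.0 <= f <= 1.0:
                raise ValueError("infiltration_means must lie in [0, 1]")
        if not (
            self.infiltration_means[0]
            > self.infiltration_means[1]
            > self.infiltration_means[2]
        ):
            raise ValueError("infiltration_means must be strictly decreasing")
        if not 0.0 <= self.censoring_fraction < 1.0:
            raise ValueError("censoring_fraction must lie in [0, 1)")
        if self.n_pten_dhs_cpgs > self.n_pten_promoter_cpgs:
            raise ValueError("DHS CpGs must be a subset of promoter CpGs")

    def cell_type_names(self) -> list[str]:
        if self.n_celltypes <= len(DEFAULT_CELL_TYPES):
            return list(DEFAULT_CELL_TYPES[: self.n_celltypes])
        extra = [
            f"Immune type {i + 1}"
            for i in range(len(DEFAULT_CELL_TYPES), self.n_celltypes)
        ]
        return list(DEFAULT_CELL_TYPES) + extra


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator (for tests and recovery checks)."""

    marker_cpg_to_celltype: dict[str, str]
    marker_gene_to_celltype: dict[str, str]
    background_cpgs: list[str]
    confounder_cpgs: list[str]
    archetypes: dict[str, pd.Series]  # per-probe archetype β levels
    cluster_profiles: pd.DataFrame | None = None  # cluster x cell type mean f
    sample_cluster_labels: pd.Series | None = None
    sample_infiltration: pd.DataFrame | None = None  # samples x cell types
    pten_truth_flags: pd.Series | None = None  # any planted PTEN event
    pten_components: pd.DataFrame | None = None
    pten_cpgs: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        labels = self.sample_cluster_labels
        if labels is not None and not set(labels.unique()) <= {1, 2, 3}:
            raise ValueError("cluster labels must lie in {1, 2, 3}")


@dataclass
class ReferencePanel:
    """Reference methylomes plus the bookkeeping the selection stage needs."""

    beta: pd.DataFrame  # probes x samples
    sample_types: pd.Series  # sample -> cell type / non_immune / tumor_line
    truth: SyntheticTruth
    annotation: pd.DataFrame  # probe_id, gene, dist_to_tss_bp, platform flags
    signature_a: pd.DataFrame  # gene, cell_type
    signature_b: pd.DataFrame
    config: SimulationConfig


@dataclass
class TumorCohort:
    beta: pd.DataFrame  # probes x samples (markers, background, PTEN promoter)
    clinical: pd.DataFrame
    expression: pd.DataFrame  # genes x samples
    pten_mutation: pd.Series  # nonsynonymous mutation flag
    pten_cn: pd.Series  # copy-number call: loss|deletion|neutral|gain
    truth: SyntheticTruth


def _draw_beta(rng: np.random.Generator, mean: np.ndarray, conc: float) -> np.ndarray:
    mean = np.clip(mean, 1e-4, 1.0 - 1e-4)
    return rng.beta(mean * conc, (1.0 - mean) * conc)


def mixture_mean_beta(f, tumor_archetype, immune_low) -> np.ndarray:
    """Expected tumor β at a marker CpG: purity-weighted two-component mix."""
    f = np.asarray(f, dtype=float)
    return (1.0 - f) * np.asarray(tumor_archetype) + f * np.asarray(immune_low)


def generate_reference_panel(config: SimulationConfig) -> ReferencePanel:
    """Simulate reference methylomes of immune, stromal and tumor-line samples.

    Marker CpGs of cell type *t* are unmethylated (archetype near 0.1) in
    type-*t* reference samples, methylated (near 0.85) in every other
    immune type, and strongly methylated (> 0.8) in all non-immune and
    tumor-line samples so they survive the stromal hypermethylation
    filter.  Background CpGs are methylated everywhere.  Confounder CpGs
    are immune-differential but *unmethylated* in stroma — they exist to
    be removed by that filter.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    types = config.cell_type_names()
    k = config.n_celltypes

    probe_counter = 0

    def next_probes(n: int) -> list[str]:
        nonlocal probe_counter
        ids = [f"cg{probe_counter + i:08d}" for i in range(n)]
        probe_counter += n
        return ids

    # ---- probes and genes -------------------------------------------------
    marker_rows: list[tuple[str, str, str]] = []  # (cpg, gene, cell type)
    for t_idx, t in enumerate(types):
        for j in range(config.n_marker_cpgs_per_type):
            gene = f"IMM{t_idx + 1:02d}G{j + 1:02d}"
            cpg = next_probes(1)[0]
            marker_rows.append((cpg, gene, t))
    for m in range(config.n_multi_cpg_genes):
        gene = f"MULTI{m + 1:02d}"
        t = types[m % k]
        for cpg in next_probes(config.n_cpgs_per_multi_gene):
            marker_rows.append((cpg, gene, t))
    confounder_rows: list[tuple[str, str, str]] = []
    for c in range(config.n_confounder_cpgs):
        gene = f"CONF{c + 1:02d}"
        t = types[c % k]
        confounder_rows.append((next_probes(1)[0], gene, t))
    background_cpgs = next_probes(config.n_background_cpgs)
    pten_cpgs = next_probes(config.n_pten_promoter_cpgs)
    pten_dhs = pten_cpgs[: config.n_pten_dhs_cpgs]

    marker_cpgs = [r[0] for r in marker_rows]
    marker_types = np.array([types.index(r[2]) for r in marker_rows])
    conf_cpgs = [r[0] for r in confounder_rows]
    conf_types = np.array([types.index(r[2]) for r in confounder_rows])

    # ---- per-probe archetype levels --------------------------------------
    n_mark = len(marker_cpgs)
    n_conf = len(conf_cpgs)
    arch = {
        "marker_low": pd.Series(
            rng.uniform(0.05, 0.20, n_mark), index=marker_cpgs
        ),
        "marker_high": pd.Series(
            rng.uniform(0.78, 0.92, n_mark), index=marker_cpgs
        ),
        "marker_nonimmune": pd.Series(
            rng.uniform(0.82, 0.95, n_mark), index=marker_cpgs
        ),
        "conf_low": pd.Series(rng.uniform(0.05, 0.20, n_conf), index=conf_cpgs),
        "conf_high": pd.Series(rng.uniform(0.78, 0.92, n_conf), index=conf_cpgs),
        "conf_nonimmune": pd.Series(
            rng.uniform(0.30, 0.50, n_conf), index=conf_cpgs
        ),
        "background": pd.Series(
            rng.uniform(0.78, 0.92, config.n_background_cpgs), index=background_cpgs
        ),
        "pten_high": pd.Series(
            rng.uniform(0.72, 0.92, config.n_pten_promoter_cpgs), index=pten_cpgs
        ),
        "pten_low": pd.Series(
            rng.uniform(0.15, 0.40, config.n_pten_promoter_cpgs), index=pten_cpgs
        ),
    }

    # ---- samples ----------------------------------------------------------
    ref_samples: list[str] = []
    ref_sample_type_idx: list[int] = []
    for t_idx in range(k):
        for i in range(config.n_ref_samples_per_type):
            ref_samples.append(f"REF_{t_idx + 1:02d}_{i + 1:02d}")
            ref_sample_type_idx.append(t_idx)
    nic_samples = [f"NIC_{i + 1:02d}" for i in range(config.n_nonimmune_samples)]
    line_samples = [f"LINE_{i + 1:02d}" for i in range(config.n_tumor_lines)]
    samples = ref_samples + nic_samples + line_samples
    sample_types = pd.Series(
        [types[i] for i in ref_sample_type_idx]
        + [NON_IMMUNE] * len(nic_samples)
        + [TUMOR_LINE] * len(line_samples),
        index=samples,
        name="sample_type",
    )
    ref_type_idx = np.array(ref_sample_type_idx)
    n_ref = len(ref_samples)
    n_other = len(nic_samples) + len(line_samples)

    # ---- archetype mean matrix (probes x samples) -------------------------
    probes = marker_cpgs + conf_cpgs + background_cpgs + pten_cpgs
    mean = np.empty((len(probes), len(samples)))
    # markers
    own = marker_types[:, None] == ref_type_idx[None, :]
    mean[:n_mark, :n_ref] = np.where(
        own,
        arch["marker_low"].to_numpy()[:, None],
        arch["marker_high"].to_numpy()[:, None],
    )
    mean[:n_mark, n_ref:] = np.repeat(
        arch["marker_nonimmune"].to_numpy()[:, None], n_other, axis=1
    )
    # confounders: same immune pattern, but unmethylated-ish in stroma/lines
    sl = slice(n_mark, n_mark + n_conf)
    own_c = conf_types[:, None] == ref_type_idx[None, :]
    mean[sl, :n_ref] = np.where(
        own_c,
        arch["conf_low"].to_numpy()[:, None],
        arch["conf_high"].to_numpy()[:, None],
    )
    mean[sl, n_ref:] = np.repeat(
        arch["conf_nonimmune"].to_numpy()[:, None], n_other, axis=1
    )
    # background + PTEN promoter (methylated high / intermediate everywhere
    # in the panel; PTEN β only matters in tumors)
    sl_bg = slice(n_mark + n_conf, n_mark + n_conf + config.n_background_cpgs)
    mean[sl_bg, :] = np.repeat(
        arch["background"].to_numpy()[:, None], len(samples), axis=1
    )
    sl_pt = slice(n_mark + n_conf + config.n_background_cpgs, len(probes))
    mean[sl_pt, :] = np.repeat(
        arch["pten_low"].to_numpy()[:, None], len(samples), axis=1
    )

    beta = pd.DataFrame(
        _draw_beta(rng, mean, config.beta_noise_concentration),
        index=pd.Index(probes, name="probe_id"),
        columns=samples,
    )

    # ---- annotation -------------------------------------------------------
    ann_rows = []
    for cpg, gene, _t in marker_rows + confounder_rows:
        ann_rows.append((cpg, gene, int(rng.integers(0, 1500)), True, True))
    signature_genes = sorted({r[1] for r in marker_rows + confounder_rows})
    # background probes exercise every exclusion route of the promoter
    # mapping: quarter promoter/shared (reach the exact test and fail it),
    # quarter too far from the TSS, quarter EPIC-only, quarter off-signature
    for i, cpg in enumerate(background_cpgs):
        group = i % 4
        if group == 0:
            gene = signature_genes[int(rng.integers(0, len(signature_genes)))]
            ann_rows.append((cpg, gene, int(rng.integers(0, 1500)), True, True))
        elif group == 1:
            gene = signature_genes[int(rng.integers(0, len(signature_genes)))]
            ann_rows.append((cpg, gene, int(rng.integers(1500, 5000)), True, True))
        elif group == 2:
            gene = signature_genes[int(rng.integers(0, len(signature_genes)))]
            ann_rows.append((cpg, gene, int(rng.integers(0, 1500)), False, True))
        else:
            ann_rows.append((cpg, f"BG{i:05d}", int(rng.integers(0, 1500)), True, True))
    for cpg in pten_cpgs:
        ann_rows.append((cpg, "PTEN", int(rng.integers(0, 1500)), True, True))
    annotation = pd.DataFrame(
        ann_rows,
        columns=["probe_id", "gene", "dist_to_tss_bp", "platform_450k", "platform_epic"],
    )

    # ---- the two gene signatures -----------------------------------------
    gene_to_type = {r[1]: r[2] for r in marker_rows + confounder_rows}
    sig_a_rows = [(g, t) for g, t in sorted(gene_to_type.items())]
    keep_b = rng.random(len(sig_a_rows)) < 0.6
    sig_b_rows = [gt for gt, kb in zip(sig_a_rows, keep_b) if kb]
    for i in range(config.n_conflict_genes):
        gene = f"CONFLICT{i + 1:02d}"
        t1, t2 = rng.choice(k, size=2, replace=False)
        sig_a_rows.append((gene, types[t1]))
        sig_b_rows.append((gene, types[t2]))
    sig_b_rows.append(("BONLY01", types[0]))
    signature_a = pd.DataFrame(sig_a_rows, columns=["gene", "cell_type"])
    signature_b = pd.DataFrame(sig_b_rows, columns=["gene", "cell_type"])

    # ---- per-cluster x cell-type infiltration profiles --------------------
    # each stratum scales a cluster-specific relative-abundance profile, so
    # strata differ in composition (rank pattern), not just overall level
    # the immune-rich stratum infiltrates every cell type at least
    # moderately (w >= 0.6), so each type's infiltration spans a wide
    # range across the cohort; the sparser strata vary freely, giving
    # the three strata distinct compositional (rank) profiles
    prof_rng = np.random.default_rng([config.seed, 2])
    w = prof_rng.uniform([[0.6], [0.3], [0.2]], [[1.8], [1.7], [1.8]], size=(3, k))
    profiles = pd.DataFrame(
        np.clip(np.array(config.infiltration_means)[:, None] * w, 0.005, 0.95),
        index=pd.Index([1, 2, 3], name="cluster"),
        columns=types,
    )

    truth = SyntheticTruth(
        marker_cpg_to_celltype={r[0]: r[2] for r in marker_rows},
        marker_gene_to_celltype={r[1]: r[2] for r in marker_rows},
        background_cpgs=list(background_cpgs),
        confounder_cpgs=list(conf_cpgs),
        archetypes=arch,
        cluster_profiles=profiles,
        pten_cpgs={"all_promoter": list(pten_cpgs), "dhs": list(pten_dhs)},
    )
    return ReferencePanel(
        beta=beta,
        sample_types=sample_types,
        truth=truth,
        annotation=annotation,
        signature_a=signature_a,
        signature_b=signature_b,
        config=config,
    )


def _censoring_upper(rates: np.ndarray, props: np.ndarray, target: float) -> float:
    """Upper bound of Uniform(0, u) censoring giving the target censoring
    fraction in expectation under the cluster mixture of exponentials."""
    if target <= 0:
        return math.inf

    def frac(u: float) -> float:
        lam_u = rates * u
        return float(np.sum(props * (1.0 - np.exp(-lam_u)) / lam_u)) - target

    return brentq(frac, 1e-9, 1e9)


def generate_tumor_cohort(
    config: SimulationConfig,
    panel: ReferencePanel,
    seed: int | None = None,
    sample_prefix: str = "Tumor",
) -> TumorCohort:
    """Simulate a tumor cohort as purity-weighted immune/tumor mixtures.

    At a marker CpG of cell type *t*, sample *s* has expected
    β = (1 − f_st)·β_line + f_st·β_immune-low, where the infiltrated
    fraction f_st is drawn around the sample's cluster × cell-type mean.
    Survival is exponential with per-cluster hazard ratios and uniform
    censoring; PTEN lesions are planted at per-cluster rates; expression
    of each signature gene declines linearly in its promoter β.

    ``seed`` defaults to the config seed; pass a different value to draw
    a fresh cohort from the same generative model (same archetypes and
    cluster profiles, new samples).
    """
    config.validate()
    if panel.truth.cluster_profiles is None:
        raise ValueError("panel truth is missing cluster profiles")
    rng = np.random.default_rng([config.seed if seed is None else seed, 1])
    types = config.cell_type_names()
    k = config.n_celltypes
    n = config.cohort_size
    samples = [f"{sample_prefix}_{i + 1:03d}" for i in range(n)]

    labels = pd.Series(
        rng.choice([1, 2, 3], size=n, p=np.asarray(config.cluster_proportions)),
        index=samples,
        name="cluster",
    )
    profiles = panel.truth.cluster_profiles
    means = profiles.loc[labels.to_numpy(), :].to_numpy()  # n x k
    c_f = config.infiltration_concentration
    infiltration = pd.DataFrame(
        rng.beta(means * c_f, (1.0 - means) * c_f),
        index=samples,
        columns=types,
    )

    arch = panel.truth.archetypes
    marker_map = panel.truth.marker_cpg_to_celltype
    marker_cpgs = list(marker_map)
    marker_type_idx = np.array([types.index(marker_map[c]) for c in marker_cpgs])
    conf_cpgs = panel.truth.confounder_cpgs
    background_cpgs = panel.truth.background_cpgs
    pten_all = panel.truth.pten_cpgs["all_promoter"]
    pten_dhs = panel.truth.pten_cpgs["dhs"]

    f_marker = infiltration.to_numpy()[:, marker_type_idx].T  # probes x samples
    mean_marker = mixture_mean_beta(
        f_marker,
        arch["marker_nonimmune"].to_numpy()[:, None],
        arch["marker_low"].to_numpy()[:, None],
    )
    # confounder CpGs sit low in tumor cells as well — roughly flat in tumors
    mean_conf = np.repeat(
        arch["conf_nonimmune"].to_numpy()[:, None], n, axis=1
    )
    mean_bg = np.repeat(arch["background"].to_numpy()[:, None], n, axis=1)

    # ---- PTEN lesions -----------------------------------------------------
    rates = np.asarray(config.pten_event_rates)[labels.to_numpy() - 1]
    has_event = rng.random(n) < rates
    mech = rng.integers(0, 3, size=n)  # 0 hyperm, 1 mutation, 2 CN loss
    hyperm_truth = has_event & (mech == 0)
    mutation = has_event & (mech == 1)
    cn_loss = has_event & (mech == 2)
    # copy-number loss frequently co-occurs with promoter hypermethylation
    cn_loss |= hyperm_truth & (rng.random(n) < 0.3)
    mean_pten = np.where(
        hyperm_truth[None, :],
        arch["pten_high"].to_numpy()[:, None],
        arch["pten_low"].to_numpy()[:, None],
    )

    probes = marker_cpgs + list(conf_cpgs) + list(background_cpgs) + list(pten_all)
    mean = np.vstack([mean_marker, mean_conf, mean_bg, mean_pten])
    beta = pd.DataFrame(
        _draw_beta(rng, mean, config.beta_noise_concentration),
        index=pd.Index(probes, name="probe_id"),
        columns=samples,
    )

    cn_call = np.full(n, "neutral", dtype=object)
    cn_call[cn_loss] = np.where(rng.random(int(cn_loss.sum())) < 0.5, "loss", "deletion")
    gain = (~cn_loss) & (rng.random(n) < 0.05)
    cn_call[gain] = "gain"
    any_event = hyperm_truth | mutation | cn_loss
    pten_components = pd.DataFrame(
        {
            "hypermethylated": hyperm_truth,
            "nonsynonymous_mutation": mutation,
            "cn_loss": cn_loss,
            "any_event": any_event,
        },
        index=samples,
    )

    # ---- expression: linear in the promoter CpG's observed β --------------
    gene_first_cpg: dict[str, str] = {}
    ann = panel.annotation.set_index("probe_id")
    for cpg in marker_cpgs:
        gene = ann.loc[cpg, "gene"]
        gene_first_cpg.setdefault(gene, cpg)  # first (lowest id) CpG drives it
    genes = sorted(gene_first_cpg)
    drv = beta.loc[[gene_first_cpg[g] for g in genes]].to_numpy()
    expression = pd.DataFrame(
        config.expression_intercept
        + config.expression_slope * drv
        + rng.normal(0.0, config.expression_noise_sd, size=drv.shape),
        index=pd.Index(genes, name="gene"),
        columns=samples,
    )

    # ---- survival + clinical ---------------------------------------------
    hr = np.asarray(config.hazard_ratios)[labels.to_numpy() - 1]
    rate = config.baseline_hazard * hr
    t_event = rng.exponential(1.0 / rate)
    cluster_rates = config.baseline_hazard * np.asarray(config.hazard_ratios)
    u = _censoring_upper(
        cluster_rates, np.asarray(config.cluster_proportions), config.censoring_fraction
    )
    t_cens = rng.uniform(0.0, u, size=n) if math.isfinite(u) else np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    til_probs = {1: (0.10, 0.30, 0.60), 2: (0.30, 0.40, 0.30), 3: (0.60, 0.30, 0.10)}
    mitf_neg = {1: 0.15, 2: 0.25, 3: 0.35}
    til = [
        rng.choice(["absent", "nonbrisk", "brisk"], p=til_probs[c]) for c in labels
    ]
    mitf = ["negative" if rng.random() < mitf_neg[c] else "positive" for c in labels]
    clinical = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "age": np.clip(rng.normal(65.0, 12.0, size=n), 25.0, 92.0),
            "sex": rng.choice(["F", "M"], size=n),
            "metastasis_type": rng.choice(
                ["lymph_node", "skin", "distant"], size=n, p=(0.5, 0.3, 0.2)
            ),
            "mitf_status": mitf,
            "til_category": til,
        },
        index=pd.Index(samples, name="sample_id"),
    )

    truth = replace(
        panel.truth,
        sample_cluster_labels=labels,
        sample_infiltration=infiltration,
        pten_truth_flags=pd.Series(any_event, index=samples, name="any_event"),
        pten_components=pten_components,
    )
    return TumorCohort(
        beta=beta,
        clinical=clinical,
        expression=expression,
        pten_mutation=pd.Series(mutation, index=samples, name="nonsynonymous_mutation"),
        pten_cn=pd.Series(cn_call, index=samples, name="cn_call"),
        truth=truth,
    )


def simulate_two_group_survival(
    n: int,
    hr: float,
    censoring_fraction: float = 0.3,
    baseline_hazard: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-arm exponential survival data with uniform censoring.

    Returns a frame with columns time, event, group ("A" reference /
    "B" with hazard ratio ``hr``).
    """
    rng = np.random.default_rng([seed, 3])
    group = np.repeat(["A", "B"], [n - n // 2, n // 2])
    rate = np.where(group == "B", baseline_hazard * hr, baseline_hazard)
    t_event = rng.exponential(1.0 / rate)
    u = _censoring_upper(
        np.array([baseline_hazard, baseline_hazard * hr]),
        np.array([1 - n // 2 / n, n // 2 / n]),
        censoring_fraction,
    )
    t_cens = rng.uniform(0.0, u, size=n) if math.isfinite(u) else np.full(n, np.inf)
    return pd.DataFrame(
        {
            "time": np.minimum(t_event, t_cens),
            "event": (t_event <= t_cens).astype(int),
            "group": group,
        }
    )


def write_simulation(panel: ReferencePanel, cohort: TumorCohort, outdir) -> None:
    """Write the simulated study as round-trippable TSV tables."""
    from . import readwrite as rw

    rw.write_beta_matrix(panel.beta, f"{outdir}/reference_beta.tsv")
    rw.write_table(
        panel.sample_types.rename_axis("sample_id").reset_index(),
        f"{outdir}/reference_sample_types.tsv",
    )
    rw.write_table(panel.annotation, f"{outdir}/annotation.tsv")
    rw.write_table(panel.signature_a, f"{outdir}/signature_a.tsv")
    rw.write_table(panel.signature_b, f"{outdir}/signature_b.tsv")
    rw.write_beta_matrix(cohort.beta, f"{outdir}/cohort_beta.tsv")
    rw.write_table(cohort.clinical.reset_index(), f"{outdir}/clinical.tsv")
    rw.write_beta_matrix(
        cohort.expression, f"{outdir}/expression.tsv", value_range=None
    )
    pten = pd.DataFrame(
        {
            "nonsynonymous_mutation": cohort.pten_mutation,
            "cn_call": cohort.pten_cn,
        }
    ).rename_axis("sample_id")
    rw.write_table(pten.reset_index(), f"{outdir}/pten_calls.tsv")
    pten_ann = pd.DataFrame(
        {
            "probe_id": cohort.truth.pten_cpgs["all_promoter"],
            "is_dhs": [
                c in set(cohort.truth.pten_cpgs["dhs"])
                for c in cohort.truth.pten_cpgs["all_promoter"]
            ],
        }
    )
    rw.write_table(pten_ann, f"{outdir}/pten_cpg_annotation.tsv")
    marker_truth = pd.DataFrame(
        sorted(cohort.truth.marker_cpg_to_celltype.items()),
        columns=["probe_id", "cell_type"],
    )
    rw.write_table(marker_truth, f"{outdir}/truth_marker_cpgs.tsv")
    truth_samples = pd.DataFrame(
        {
            "cluster": cohort.truth.sample_cluster_labels,
            "pten_any_event": cohort.truth.pten_truth_flags,
        }
    ).rename_axis("sample_id")
    rw.write_table(truth_samples.reset_index(), f"{outdir}/truth_samples.tsv")
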