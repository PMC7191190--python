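"""Immune cell type-specific CpG selection from reference methylomes.

The selection funnel, applied to a combined immune gene signature and a
reference panel of immune / non-immune methylomes:

1. merge two gene -> cell-type signatures, dropping genes the sources
   type differently;
2. map signature genes to promoter CpGs (|distance to TSS| < 1500 bp,
   probe present on both the 450K and EPIC platforms);
3. dichotomize β at 0.3 (unmethylated < 0.3 ≤ methylated) and keep CpGs
   whose methylated/unmethylated proportions differ across the reference
   immune cell types (r x 2 exact test, Benjamini-Hochberg FDR < 0.01);
4. keep CpGs hypermethylated in non-immune cells and tumor lines
   (β > 0.7 in more than 98% of those samples; 90% in pan-cancer mode);
5. collapse to one CpG per gene: smallest p, ties broken by larger
   reference β range, then lexicographically smallest probe ID.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .exact import fisher_exact_r_by_2

__all__ = [
    "SelectionParams",
    "combine_signatures",
    "map_promoter_cpgs",
    "binarize_beta",
    "fisher_differential",
    "nonimmune_hypermethylation_filter",
    "select_best_cpg_per_gene",
    "run_selection",
]

NONIMMUNE_LABELS = ("non_immune", "tumor_line")

_ANNOTATION_COLUMNS = (
    "probe_id",
    "gene",
    "dist_to_tss_bp",
    "platform_450k",
    "platform_epic",
)


@dataclass
class SelectionParams:
    tss_max_distance_bp: int = 1500
    binarize_threshold: float = 0.3
    fdr_threshold: float = 0.01
    nonimmune_beta_threshold: float = 0.7
    nonimmune_sample_fraction: float = 0.98  # 0.90 in pan-cancer mode
    max_missing_fraction: float = 0.20
    seed: int = 0  # drives the Monte-Carlo fallback of the exact test

    def __post_init__(self) -> None:
        for name in (
            "binarize_threshold",
            "fdr_threshold",
            "nonimmune_beta_threshold",
            "nonimmune_sample_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.tss_max_distance_bp <= 0:
            raise ValueError("tss_max_distance_bp must be positive")

    @classmethod
    def for_mode(cls, mode: str, **overrides) -> "SelectionParams":
        """'melanoma' (stroma filter at 98%) or 'pancancer' (90%)."""
        if mode not in ("melanoma", "pancancer"):
            raise ValueError(f"unknown mode {mode!r}")
        frac = 0.98 if mode == "melanoma" else 0.90
        overrides.setdefault("nonimmune_sample_fraction", frac)
        return cls(**overrides)


def combine_signatures(
    sig_a: pd.DataFrame, sig_b: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Union of two (gene, cell_type) signatures with conflict removal.

    Genes typed identically in both sources are kept once; genes typed
    differently are removed entirely.  Returns the merged signature and
    a report with the conflict count.
    """
    for name, sig in (("sig_a", sig_a), ("sig_b", sig_b)):
        if sig.empty:
            raise ValueError(f"{name} is empty")
        if not {"gene", "cell_type"} <= set(sig.columns):
            raise ValueError(f"{name} must have columns gene, cell_type")
    a = sig_a.drop_duplicates(["gene", "cell_type"]).set_index("gene")["cell_type"]
    b = sig_b.drop_duplicates(["gene", "cell_type"]).set_index("gene")["cell_type"]
    for name, s in (("sig_a", a), ("sig_b", b)):
        if s.index.duplicated().any():
            raise ValueError(f"{name} assigns a gene to multiple cell types")
    shared = a.index.intersection(b.index)
    conflicts = shared[a.loc[shared] != b.loc[shared]]
    merged = pd.concat([a, b[~b.index.isin(a.index)]]).drop(conflicts).sort_index()
    if merged.empty:
        raise ValueError("no genes remain after conflict removal")
    combined = merged.rename("cell_type").rename_axis("gene").reset_index()
    report = {
        "n_genes_a": int(a.size),
        "n_genes_b": int(b.size),
        "n_conflicts_removed": int(conflicts.size),
        "n_genes_combined": int(combined.shape[0]),
        "n_celltypes": int(combined["cell_type"].nunique()),
    }
    return combined, report


def map_promoter_cpgs(
    signature: pd.DataFrame,
    annotation: pd.DataFrame,
    params: SelectionParams | None = None,
) -> pd.DataFrame:
    """Candidate CpGs: promoter probes of signature genes shared by both
    array platforms (|dist to TSS| strictly below the cutoff)."""
    params = params or SelectionParams()
    missing = set(_ANNOTATION_COLUMNS) - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation is missing columns: {sorted(missing)}")
    ann = annotation.merge(signature[["gene", "cell_type"]], on="gene", how="inner")
    keep = (
        (ann["dist_to_tss_bp"].abs() < params.tss_max_distance_bp)
        & ann["platform_450k"].astype(bool)
        & ann["platform_epic"].astype(bool)
    )
    out = ann.loc[keep, ["probe_id", "gene", "cell_type", "dist_to_tss_bp"]]
    return out.reset_index(drop=True)


def binarize_beta(beta: pd.DataFrame, threshold: float = 0.3) -> pd.DataFrame:
    """β < threshold -> 0 (unmethylated); β ≥ threshold -> 1; NaN stays NaN."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    values = beta.to_numpy(dtype=float)
    out = np.where(np.isnan(values), np.nan, (values >= threshold).astype(float))
    return pd.DataFrame(out, index=beta.index, columns=beta.columns)


def fisher_differential(
    binary: pd.DataFrame,
    cell_types: pd.Series,
    params: SelectionParams | None = None,
) -> pd.DataFrame:
    """Per-CpG exact test of methylation-bin homogeneity across cell types.

    ``binary`` holds 0/1/NaN calls (probes x reference immune samples);
    ``cell_types`` maps each sample to its type.  Missing calls are
    dropped pairwise; CpGs missing in more than ``max_missing_fraction``
    of samples are flagged and excluded from the FDR ranking.  Identical
    count tables share one exact-test evaluation.
    """
    params = params or SelectionParams()
    cell_types = cell_types.loc[binary.columns]
    groups = sorted(cell_types.unique())
    if len(groups) < 2:
        raise ValueError("need at least two cell types")
    if (cell_types.value_counts() < 2).any():
        raise ValueError("need at least two samples per cell type")
    cols_by_type = {g: np.flatnonzero((cell_types == g).to_numpy()) for g in groups}

    values = binary.to_numpy(dtype=float)
    n_samples = values.shape[1]
    cache: dict[bytes, float] = {}
    rows = []
    for i, cpg in enumerate(binary.index):
        row = values[i]
        n_miss = int(np.isnan(row).sum())
        if n_samples - n_miss == 0 or n_miss / n_samples > params.max_missing_fraction:
            rows.append((cpg, np.nan, n_miss, True))
            continue
        table = np.empty((len(groups), 2), dtype=np.int64)
        for gi, g in enumerate(groups):
            vals = row[cols_by_type[g]]
            vals = vals[~np.isnan(vals)]
            meth = int(vals.sum())
            table[gi] = (len(vals) - meth, meth)
        key = table.tobytes()
        if key not in cache:
            cache[key] = fisher_exact_r_by_2(table, seed=params.seed).p
        rows.append((cpg, cache[key], n_miss, False))

    out = pd.DataFrame(
        rows, columns=["probe_id", "p", "n_missing", "excluded_missing"]
    ).set_index("probe_id")
    out["fdr"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "fdr"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def nonimmune_hypermethylation_filter(
    beta_nonimmune: pd.DataFrame, params: SelectionParams | None = None
) -> pd.Series:
    """True where the fraction of non-immune samples with β strictly above
    the level threshold strictly exceeds the sample-fraction threshold."""
    params = params or SelectionParams()
    if beta_nonimmune.shape[1] < 1:
        raise ValueError("need at least one non-immune sample")
    values = beta_nonimmune.to_numpy(dtype=float)
    high = (values > params.nonimmune_beta_threshold).sum(axis=1)
    n_obs = (~np.isnan(values)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac = np.where(n_obs > 0, high / np.maximum(n_obs, 1), np.nan)
    passed = (n_obs > 0) & (frac > params.nonimmune_sample_fraction)
    return pd.Series(passed, index=beta_nonimmune.index, name="nonimmune_pass")


def select_best_cpg_per_gene(candidates: pd.DataFrame) -> pd.DataFrame:
    """One CpG per gene: minimal p, then larger reference β range, then
    lexicographically smallest probe ID.  Deterministic."""
    if candidates.empty:
        return candidates
    ranked = candidates.sort_values(
        ["gene", "p", "beta_range", "probe_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    return ranked.groupby("gene", sort=True).head(1).reset_index(drop=True)


def run_selection(
    beta: pd.DataFrame,
    sample_types: pd.Series,
    signature_a: pd.DataFrame,
    signature_b: pd.DataFrame,
    annotation: pd.DataFrame,
    params: SelectionParams | None = None,
    nonimmune_labels=NONIMMUNE_LABELS,
) -> tuple[pd.DataFrame, dict]:
    """Full selection funnel; returns (gene-CpG pairs, funnel report).

    The pairs frame has columns gene, probe_id (named ``cpg`` in the TSV
    writer), cell_type, p, fdr; the report counts survivors of each step.
    """
    params = params or SelectionParams()
    combined, report = combine_signatures(signature_a, signature_b)

    candidates = map_promoter_cpgs(combined, annotation, params)
    candidates = candidates[candidates["probe_id"].isin(beta.index)]
    report["n_candidate_cpgs"] = int(candidates.shape[0])
    report["n_candidate_genes"] = int(candidates["gene"].nunique())
    if candidates.empty:
        raise ValueError("no candidate CpGs map into the β matrix")

    sample_types = sample_types.loc[beta.columns]
    immune_cols = beta.columns[~sample_types.isin(nonimmune_labels)]
    nonimmune_cols = beta.columns[sample_types.isin(nonimmune_labels)]
    cand_beta = beta.loc[candidates["probe_id"].unique()]

    binary = binarize_beta(cand_beta[immune_cols], params.binarize_threshold)
    tests = fisher_differential(binary, sample_types.loc[immune_cols], params)
    differential = tests.index[tests["fdr"] < params.fdr_threshold]
    report["n_after_fisher"] = int(differential.size)

    nonimm = nonimmune_hypermethylation_filter(
        cand_beta.loc[differential, nonimmune_cols], params
    )
    surviving = nonimm.index[nonimm]
    report["n_after_nonimmune_filter"] = int(surviving.size)

    ref = cand_beta.loc[surviving, immune_cols]
    beta_range = (ref.max(axis=1) - ref.min(axis=1)).rename("beta_range")
    final_cand = (
        candidates[candidates["probe_id"].isin(surviving)]
        .drop_duplicates("probe_id")
        .merge(tests[["p", "fdr"]], left_on="probe_id", right_index=True)
        .merge(beta_range, left_on="probe_id", right_index=True)
    )
    pairs = select_best_cpg_per_gene(final_cand)
    pairs = pairs[["gene", "probe_id", "cell_type", "p", "fdr", "beta_range"]]
    pairs = pairs.sort_values(["cell_type", "gene"]).reset_index(drop=True)
    report["n_pairs"] = int(pairs.shape[0])
    report["n_celltypes_final"] = int(pairs["cell_type"].nunique())
    return pairs, report
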