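"""Per-cell-type methylation and expression scores.

A sample's methylation score for a cell type is the median β over that
type's signature CpGs — low score means the type's promoters are
unmethylated in the bulk sample, i.e. the cell type is inferred present.
Expression scores are the per-sample median of (optionally median-
centered) signature gene expression.  Methylation scores of 0.7 and
below count as "not hypermethylated"; strictly above 0.7 as
"hypermethylated".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScoreMatrix",
    "methylation_score",
    "expression_score",
    "dichotomize_value",
    "dichotomize_score",
]

logger = logging.getLogger(__name__)

HYPERMETHYLATED = "hypermethylated"
NOT_HYPERMETHYLATED = "not_hypermethylated"


@dataclass
class ScoreMatrix:
    values: pd.DataFrame  # samples x cell types
    modality: str  # "methylation" | "expression"
    centered: bool = False

    def __post_init__(self) -> None:
        if self.modality not in ("methylation", "expression"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.centered and self.modality != "expression":
            raise ValueError("centered scores only apply to expression")
        if self.modality == "methylation":
            v = self.values.to_numpy(dtype=float)
            ok = np.isnan(v) | ((v >= 0.0) & (v <= 1.0))
            if not ok.all():
                raise ValueError("methylation scores must lie in [0, 1]")


def methylation_score(beta: pd.DataFrame, pairs: pd.DataFrame) -> ScoreMatrix:
    """Median β per (sample, cell type) over the type's signature CpGs.

    ``pairs`` needs columns probe_id and cell_type (a selected gene-CpG
    set).  Cell types with no CpG present in the matrix yield an
    all-missing column, logged — mirrors screens where no CpG survived
    filtering for a cohort.
    """
    if pairs.empty:
        raise ValueError("empty gene-CpG pair set")
    cols = {}
    for cell_type, grp in pairs.groupby("cell_type", sort=True):
        cpgs = pd.Index(grp["probe_id"].unique()).intersection(beta.index)
        if cpgs.empty:
            logger.warning("no CpG of cell type %r present; score missing", cell_type)
            cols[cell_type] = pd.Series(np.nan, index=beta.columns)
        else:
            cols[cell_type] = beta.loc[cpgs].median(axis=0, skipna=True)
    values = pd.DataFrame(cols)
    values.index.name = "sample_id"
    return ScoreMatrix(values=values, modality="methylation")


def expression_score(
    expression: pd.DataFrame, signature: pd.DataFrame, center: bool = True
) -> ScoreMatrix:
    """Median expression per (sample, cell type) over signature genes.

    Gene symbols are matched case-sensitively after stripping
    surrounding whitespace.  With ``center=True`` each gene is first
    median-centered across samples (cohort mode); pan-cancer analyses
    use ``center=False``.
    """
    expr = expression.copy()
    expr.index = expr.index.astype(str).str.strip()
    sig = signature.assign(gene=signature["gene"].astype(str).str.strip())
    genes = pd.Index(sig["gene"].unique()).intersection(expr.index)
    if genes.empty:
        raise ValueError("no overlap between signature genes and expression matrix")
    if center:
        expr = expr.sub(expr.median(axis=1), axis=0)
    cols = {}
    for cell_type, grp in sig.groupby("cell_type", sort=True):
        g = pd.Index(grp["gene"].unique()).intersection(expr.index)
        if g.empty:
            logger.warning("no gene of cell type %r present; score missing", cell_type)
            cols[cell_type] = pd.Series(np.nan, index=expr.columns)
        else:
            cols[cell_type] = expr.loc[g].median(axis=0, skipna=True)
    values = pd.DataFrame(cols)
    values.index.name = "sample_id"
    return ScoreMatrix(values=values, modality="expression", centered=center)


def dichotomize_value(score: float, threshold: float = 0.7) -> str:
    """β strictly above the threshold is hypermethylated; at or below, not."""
    if np.isnan(score):
        return ""
    return HYPERMETHYLATED if score > threshold else NOT_HYPERMETHYLATED


def dichotomize_score(scores: ScoreMatrix, threshold: float = 0.7) -> pd.DataFrame:
    """Categorical samples x cell types frame of hypermethylation calls."""
    if scores.modality != "methylation":
        raise ValueError("dichotomization applies to methylation scores only")
    return scores.values.map(lambda v: dichotomize_value(v, threshold))
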