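"""PTEN promoter hypermethylation calls and alteration-event integration.

A tumor is called PTEN promoter-hypermethylated when strictly more than
10% of its DHS (DNase-hypersensitivity-site) promoter CpGs have
β > 0.7 *and* the median β over all PTEN promoter CpGs is strictly
above 0.5.  A PTEN alteration event is promoter hypermethylation OR
nonsynonymous mutation OR copy-number loss/deletion.

The generic gene machinery takes any promoter/DHS CpG annotation;
parameters are tuned for and validated on PTEN only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PtenCpGSet",
    "call_pten_hypermethylation",
    "call_pten_cohort",
    "integrate_pten_events",
    "pten_event_summary",
]

logger = logging.getLogger(__name__)

CN_LOSS_CATEGORIES = ("loss", "deletion")
CN_CATEGORIES = CN_LOSS_CATEGORIES + ("neutral", "gain")


@dataclass(frozen=True)
class PtenCpGSet:
    all_promoter_cpgs: tuple[str, ...]
    dhs_cpgs: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.all_promoter_cpgs or not self.dhs_cpgs:
            raise ValueError("both CpG sets must be non-empty")
        if not set(self.dhs_cpgs) <= set(self.all_promoter_cpgs):
            raise ValueError("DHS CpGs must be a subset of promoter CpGs")

    @classmethod
    def from_annotation(cls, annotation: pd.DataFrame) -> "PtenCpGSet":
        """Build from a table with columns probe_id, is_dhs."""
        probes = tuple(annotation["probe_id"])
        dhs = tuple(annotation.loc[annotation["is_dhs"].astype(bool), "probe_id"])
        return cls(all_promoter_cpgs=probes, dhs_cpgs=dhs)


def call_pten_hypermethylation(
    sample_beta: pd.Series,
    cpgs: PtenCpGSet,
    dhs_fraction_threshold: float = 0.10,
    dhs_beta_threshold: float = 0.7,
    median_threshold: float = 0.5,
    min_dhs_cpgs: int = 5,
) -> bool | None:
    """Hypermethylation call for one sample; None when undetermined.

    True iff (# DHS CpGs with β > 0.7) / (# non-missing DHS CpGs)
    strictly exceeds 10% AND median β over all promoter CpGs strictly
    exceeds 0.5.  Fewer than ``min_dhs_cpgs`` informative DHS CpGs gives
    an undetermined (None) call, logged.
    """
    dhs = sample_beta.reindex(list(cpgs.dhs_cpgs)).dropna()
    if len(dhs) < min_dhs_cpgs:
        logger.warning(
            "sample %s: only %d informative DHS CpGs (< %d); undetermined",
            sample_beta.name, len(dhs), min_dhs_cpgs,
        )
        return None
    frac_high = float((dhs > dhs_beta_threshold).sum()) / len(dhs)
    promoter = sample_beta.reindex(list(cpgs.all_promoter_cpgs)).dropna()
    med = float(promoter.median())
    return bool(frac_high > dhs_fraction_threshold and med > median_threshold)


def call_pten_cohort(beta: pd.DataFrame, cpgs: PtenCpGSet, **kwargs) -> pd.Series:
    """Per-sample hypermethylation calls over the columns of ``beta``."""
    calls = {s: call_pten_hypermethylation(beta[s], cpgs, **kwargs) for s in beta.columns}
    return pd.Series(calls, name="hypermethylated", dtype=object)


def _align_bool(flags: pd.Series | None, index: pd.Index, name: str) -> tuple[pd.Series, pd.Series]:
    """Align a flag series to the cohort index; missing modality -> False
    with a per-sample completeness marker."""
    if flags is None:
        return (
            pd.Series(False, index=index, name=name),
            pd.Series(False, index=index),
        )
    if flags.index.duplicated().any():
        dup = flags.index[flags.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs in {name}: {dup[:5]}")
    aligned = flags.reindex(index)
    present = aligned.notna()
    filled = aligned.map(lambda v: bool(v) if pd.notna(v) else False)
    return filled.rename(name), present


def integrate_pten_events(
    hypermethylated: pd.Series,
    mutation: pd.Series | None = None,
    cn_call: pd.Series | None = None,
) -> pd.DataFrame:
    """Combine per-sample PTEN lesion modalities into alteration events.

    ``cn_call`` may be boolean or categorical (loss/deletion count as
    events).  Missing modalities are treated as False and reflected in
    the ``complete`` column.
    """
    index = hypermethylated.index
    if index.duplicated().any():
        raise ValueError("duplicate sample IDs in hypermethylation calls")
    hyper_present = hypermethylated.notna()
    hyper = hypermethylated.map(lambda v: bool(v) if pd.notna(v) else False).rename(
        "hypermethylated"
    )

    mut, mut_present = _align_bool(mutation, index, "nonsynonymous_mutation")
    if cn_call is not None and cn_call.dtype == object:
        unknown = set(cn_call.dropna().unique()) - set(CN_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown copy-number categories: {sorted(unknown)}")
        cn_bool = cn_call.map(lambda v: v in CN_LOSS_CATEGORIES if pd.notna(v) else np.nan)
    else:
        cn_bool = cn_call
    cn, cn_present = _align_bool(cn_bool, index, "cn_loss")

    out = pd.DataFrame({"hypermethylated": hyper, "nonsynonymous_mutation": mut, "cn_loss": cn})
    out["any_event"] = out.any(axis=1)
    out["complete"] = hyper_present & mut_present & cn_present
    out.index.name = "sample_id"
    return out


def pten_event_summary(status: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-cluster composition of PTEN alteration events."""
    labels = labels.loc[status.index]
    rows = []
    for cluster, grp in status.groupby(labels):
        n = len(grp)
        rows.append(
            {
                "cluster": cluster,
                "n_samples": n,
                "n_hypermethylated": int(grp["hypermethylated"].sum()),
                "n_mutation": int(grp["nonsynonymous_mutation"].sum()),
                "n_cn_loss": int(grp["cn_loss"].sum()),
                "n_any_event": int(grp["any_event"].sum()),
                "frac_any_event": float(grp["any_event"].mean()),
            }
        )
    return pd.DataFrame(rows).set_index("cluster")
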