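"""Cluster-level statistics: Δβ contrasts with Kruskal-Wallis + Dunn post
hoc, categorical associations, and Cox / Kaplan-Meier survival models.

Multiple-testing correction is Benjamini-Hochberg throughout.  For the
Δβ balloon-plot-style table the FDR is computed across cell types
separately within each cluster-pair comparison.  Cox models use Efron
tie handling (lifelines) with Wald 95% confidence intervals; groups
without events are flagged non-estimable rather than raising.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact, kruskal, norm, rankdata
from scipy.stats.contingency import expected_freq
from scipy.stats import random_table
from statsmodels.stats.multitest import multipletests

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .scoring import HYPERMETHYLATED, NOT_HYPERMETHYLATED, ScoreMatrix

__all__ = [
    "dunn_posthoc",
    "delta_beta_contrasts",
    "categorical_association",
    "association_batch",
    "fit_survival",
    "cox_screen",
    "km_logrank",
    "AssociationResult",
    "KMResult",
]

ENDPOINTS = ("DMFS", "DSS", "OS")


# ---------------------------------------------------------------------------
# rank-based post hoc machinery


def dunn_posthoc(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn's pairwise z-tests on joint ranks, with tie correction.

    z_ab = (Rbar_a - Rbar_b) / sqrt[(N(N+1)/12 - T/(12(N-1))) (1/n_a + 1/n_b)]
    where T = sum over tied groups of (t^3 - t).  Two-sided normal p.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = ~np.isnan(values)
    values, groups = values[ok], groups[ok]
    n = len(values)
    ranks = rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_factor = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    levels = sorted(pd.unique(groups))
    mean_rank = {g: ranks[groups == g].mean() for g in levels}
    size = {g: int((groups == g).sum()) for g in levels}
    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            se = np.sqrt(var_factor * (1.0 / size[a] + 1.0 / size[b]))
            z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "z": z,
                    "p": float(2.0 * norm.sf(abs(z))),
                }
            )
    return pd.DataFrame(rows)


def delta_beta_contrasts(
    scores: ScoreMatrix, labels: pd.Series, min_group_size: int = 3
) -> pd.DataFrame:
    """Pairwise cluster contrasts of per-cell-type scores.

    Per cell type: Kruskal-Wallis over clusters, Dunn pairwise z-tests,
    and |Δ median score| per cluster pair; BH-FDR across cell types
    within each cluster pair.  Clusters below ``min_group_size`` are
    excluded with a warning.
    """
    labels = labels.loc[scores.values.index]
    counts = labels.value_counts()
    small = counts.index[counts < min_group_size].tolist()
    if small:
        warnings.warn(f"excluding clusters with < {min_group_size} samples: {small}")
    keep = ~labels.isin(small)
    labels = labels[keep]
    if labels.nunique() < 2:
        raise ValueError("need at least two clusters of sufficient size")
    values = scores.values.loc[labels.index]

    rows = []
    for cell_type in values.columns:
        v = values[cell_type].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        g = labels.to_numpy()[ok]
        v = v[ok]
        if len(np.unique(g)) < 2 or np.ptp(v) == 0:
            continue
        kw_p = float(kruskal(*[v[g == c] for c in np.unique(g)]).pvalue)
        dunn = dunn_posthoc(v, g)
        med = {c: float(np.median(v[g == c])) for c in np.unique(g)}
        for d in dunn.itertuples(index=False):
            rows.append(
                {
                    "cell_type": cell_type,
                    "cluster_a": d.group_a,
                    "cluster_b": d.group_b,
                    "abs_delta_beta": abs(med[d.group_a] - med[d.group_b]),
                    "kw_p": kw_p,
                    "dunn_z": d.z,
                    "dunn_p": d.p,
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["dunn_fdr"] = np.nan
    for _, idx in out.groupby(["cluster_a", "cluster_b"]).groups.items():
        out.loc[idx, "dunn_fdr"] = multipletests(
            out.loc[idx, "dunn_p"], method="fdr_bh"
        )[1]
    return out.sort_values(["cluster_a", "cluster_b", "cell_type"]).reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# categorical associations


@dataclass
class AssociationResult:
    p: float
    method: str  # "fisher" | "chi2" | "chi2-mc"
    statistic: float | None
    table: pd.DataFrame


def categorical_association(
    labels: pd.Series,
    annotation: pd.Series,
    mc_draws: int = 10_000,
    seed: int = 0,
) -> AssociationResult:
    """Association between cluster labels and a categorical annotation.

    2x2 tables use Fisher's exact test; larger tables Pearson chi-square
    without continuity correction, replaced by a seeded Monte-Carlo
    exact p (margin-preserving random tables) when any expected count
    falls below 5.
    """
    annotation = annotation.loc[labels.index]
    table = pd.crosstab(labels, annotation)
    table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("degenerate table: need >= 2 populated rows and columns")
    counts = table.to_numpy()
    if counts.shape == (2, 2):
        _, p = fisher_exact(counts, alternative="two-sided")
        return AssociationResult(p=float(p), method="fisher", statistic=None, table=table)
    stat, p, _, expected = chi2_contingency(counts, correction=False)
    if (expected >= 5).all():
        return AssociationResult(p=float(p), method="chi2", statistic=float(stat), table=table)
    rng = np.random.default_rng([seed, 5])
    draws = random_table(counts.sum(axis=1), counts.sum(axis=0)).rvs(
        mc_draws, random_state=rng, method="patefield"
    )
    exp = expected_freq(counts)
    stats_mc = ((draws - exp) ** 2 / exp).sum(axis=(1, 2))
    p_mc = (1.0 + float(np.count_nonzero(stats_mc >= stat - 1e-12))) / (1.0 + mc_draws)
    return AssociationResult(p=p_mc, method="chi2-mc", statistic=float(stat), table=table)


def association_batch(
    labels: pd.Series, annotations: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Run categorical_association per annotation column with BH-FDR."""
    rows = []
    for col in annotations.columns:
        res = categorical_association(labels, annotations[col], seed=seed)
        rows.append({"annotation": col, "p": res.p, "method": res.method})
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# survival


def _term_rows(cph: CoxPHFitter, model: str, endpoint: str) -> list[dict]:
    summ = cph.summary
    rows = []
    for term, r in summ.iterrows():
        rows.append(
            {
                "term": term if isinstance(term, str) else str(term),
                "hr": float(r["exp(coef)"]),
                "ci_low": float(r["exp(coef) lower 95%"]),
                "ci_high": float(r["exp(coef) upper 95%"]),
                "p": float(r["p"]),
                "model": model,
                "endpoint": endpoint,
                "estimable": True,
            }
        )
    return rows


def fit_survival(
    clinical: pd.DataFrame,
    groups: pd.Series,
    covariates: list[str] | None = None,
    endpoint: str = "DSS",
    reference: str | None = None,
) -> pd.DataFrame:
    """Cox proportional-hazards fit of group membership (plus covariates).

    The reference level is the smallest group label (cluster 1 /
    not-hypermethylated).  Group levels with zero events are flagged
    non-estimable (NaN hazard ratio) and their samples excluded from the
    fit rather than raising on the monotone likelihood.
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {ENDPOINTS}")
    covariates = covariates or []
    df = clinical.loc[groups.index, ["time", "event"] + covariates].copy()
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not set(df["event"].unique()) <= {0, 1}:
        raise ValueError("event indicator must be 0/1")
    groups = groups.loc[df.index].astype(str)
    levels = sorted(groups.unique())
    if reference is not None:
        reference = str(reference)
        if reference not in levels:
            raise ValueError(f"reference level {reference!r} absent from groups")
        levels = [reference] + [l for l in levels if l != reference]
    else:
        reference = levels[0]

    rows: list[dict] = []
    events_by_level = df.groupby(groups)["event"].sum()
    bad_levels = [l for l in levels if events_by_level.get(l, 0) == 0]
    model = "multivariate" if covariates else "univariate"
    for level in levels[1:]:
        if level in bad_levels or reference in bad_levels:
            rows.append(
                {
                    "term": f"group[{level}]",
                    "hr": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p": np.nan,
                    "model": model,
                    "endpoint": endpoint,
                    "estimable": False,
                }
            )
    usable = [l for l in levels if l not in bad_levels]
    if reference in bad_levels or len(usable) < 2:
        return pd.DataFrame(rows)

    mask = groups.isin(usable)
    design = pd.get_dummies(
        groups[mask].astype(pd.CategoricalDtype(usable)),
        prefix="group", prefix_sep="[", dtype=float,
    ).iloc[:, 1:]
    design.columns = [c + "]" for c in design.columns]
    X = pd.concat([df.loc[mask, ["time", "event"]], design], axis=1)
    for cov in covariates:
        col = df.loc[mask, cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=cov, dtype=float).iloc[:, 1:]
            X = pd.concat([X, dummies], axis=1)
        else:
            X[cov] = col.astype(float)
    cph = CoxPHFitter()
    try:
        cph.fit(X, duration_col="time", event_col="event")
    except Exception:
        for level in usable[1:]:
            rows.append(
                {
                    "term": f"group[{level}]",
                    "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                    "model": model, "endpoint": endpoint, "estimable": False,
                }
            )
        return pd.DataFrame(rows)
    rows.extend(_term_rows(cph, model, endpoint))
    return pd.DataFrame(rows)


def cox_screen(
    dichotomized: pd.DataFrame,
    clinical: pd.DataFrame,
    endpoint: str = "OS",
    fdr_threshold: float = 0.1,
) -> pd.DataFrame:
    """Univariate Cox per cell type on dichotomized methylation scores.

    One model per column of ``dichotomized`` (categories hypermethylated
    vs not), BH correction across cell types, significance at adjusted
    p < 0.1, and an HR size annotation (large: HR ≥ 1.5 or ≤ 0.66).
    Non-estimable cell types (a category with no samples or no events)
    are kept with NaN estimates.
    """
    rows = []
    for cell_type in dichotomized.columns:
        calls = dichotomized[cell_type].replace("", np.nan).dropna()
        order = pd.Series(
            pd.Categorical(calls, categories=[NOT_HYPERMETHYLATED, HYPERMETHYLATED])
        , index=calls.index)
        n_cat = order.value_counts()
        if (
            len(calls) < 4
            or (n_cat < 2).any()
            or calls.nunique() < 2
        ):
            rows.append({"cell_type": cell_type, "hr": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p": np.nan, "estimable": False})
            continue
        fit = fit_survival(
            clinical, order.astype(str), endpoint=endpoint,
            reference=NOT_HYPERMETHYLATED,
        )
        if fit.empty or not fit.iloc[0]["estimable"]:
            rows.append({"cell_type": cell_type, "hr": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p": np.nan, "estimable": False})
            continue
        r = fit.iloc[0]
        rows.append({"cell_type": cell_type, "hr": r["hr"], "ci_low": r["ci_low"],
                     "ci_high": r["ci_high"], "p": r["p"], "estimable": True})
    out = pd.DataFrame(rows).set_index("cell_type")
    out["fdr"] = np.nan
    ok = out["estimable"] & out["p"].notna()
    if ok.any():
        out.loc[ok, "fdr"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out["significant"] = out["fdr"] < fdr_threshold
    out["hr_size"] = np.where(
        out["hr"].isna(), "",
        np.where((out["hr"] >= 1.5) | (out["hr"] <= 0.66), "large", "small"),
    )
    return out


@dataclass
class KMResult:
    curves: dict  # group -> DataFrame(timeline, survival)
    at_risk: pd.DataFrame  # groups x horizon years
    logrank_p: float | None
    logrank_stat: float | None


def km_logrank(
    clinical: pd.DataFrame,
    groups: pd.Series,
    horizons=(0, 2, 4, 6, 8, 10),
    display_horizon: float = 10.0,
) -> KMResult:
    """Kaplan-Meier curves per group plus the log-rank test.

    ``display_horizon`` only truncates the reported curves (plotting
    convention); the log-rank test uses all follow-up.
    """
    groups = groups.loc[clinical.index].astype(str)
    df = clinical[["time", "event"]]
    curves = {}
    at_risk_rows = {}
    for g in sorted(groups.unique()):
        sub = df[groups == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"], label=str(g))
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["timeline", "survival"]
        curves[g] = sf[sf["timeline"] <= display_horizon].reset_index(drop=True)
        at_risk_rows[g] = [
            int((sub["time"] >= h).sum()) for h in horizons
        ]
    at_risk = pd.DataFrame(
        at_risk_rows, index=pd.Index(horizons, name="years")
    ).T.rename_axis("group")
    if groups.nunique() < 2:
        return KMResult(curves=curves, at_risk=at_risk, logrank_p=None, logrank_stat=None)
    res = multivariate_logrank_test(df["time"], groups, df["event"])
    return KMResult(
        curves=curves,
        at_risk=at_risk,
        logrank_p=float(res.p_value),
        logrank_stat=float(res.test_statistic),
    )
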