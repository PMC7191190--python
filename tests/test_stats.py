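"""Δβ contrasts, Dunn post hoc, categorical associations, survival models."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kruskal, kstest

import immunometh as im
from immunometh.scoring import ScoreMatrix
from immunometh.stats import dunn_posthoc

from oracles import bh_fdr, dunn_z_pairs, kruskal_h


class TestKruskalDunn:
    def test_textbook_kw_h(self):
        groups = ([1, 2, 3], [4, 5, 6], [7, 8, 9])
        h = kruskal(*groups).statistic
        assert h == pytest.approx(7.2, abs=1e-12)
        assert h == pytest.approx(kruskal_h(groups), abs=1e-12)
        assert kruskal(*groups).pvalue == pytest.approx(0.02732, abs=1e-4)

    def test_dunn_matches_rank_arithmetic_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(9, 30))
            values = rng.uniform(size=n).round(1)  # rounding forces ties
            groups = rng.choice(["a", "b", "c"], size=n)
            while len(set(groups)) < 3:
                groups = rng.choice(["a", "b", "c"], size=n)
            ours = dunn_posthoc(values, groups)
            expected = dunn_z_pairs(values, groups)
            for row in ours.itertuples(index=False):
                assert row.z == pytest.approx(
                    expected[(row.group_a, row.group_b)], abs=1e-10
                )

    def test_bh_fdr_matches_naive_oracle(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=40)
        assert multipletests(p, method="fdr_bh")[1] == pytest.approx(
            bh_fdr(p), abs=1e-12
        )


class TestDeltaBeta:
    @pytest.fixture()
    def scores_and_labels(self, cohort, selected_pairs):
        pairs, _ = selected_pairs
        scores = im.methylation_score(cohort.beta, pairs)
        return scores, cohort.truth.sample_cluster_labels

    def test_abs_delta_beta_is_median_difference(self, scores_and_labels):
        scores, labels = scores_and_labels
        table = im.delta_beta_contrasts(scores, labels)
        row = table.iloc[0]
        a = scores.values.loc[labels == row["cluster_a"], row["cell_type"]].median()
        b = scores.values.loc[labels == row["cluster_b"], row["cell_type"]].median()
        assert row["abs_delta_beta"] == pytest.approx(abs(a - b), abs=1e-12)

    def test_extreme_cluster_pair_has_largest_contrast(self, scores_and_labels):
        scores, labels = scores_and_labels
        table = im.delta_beta_contrasts(scores, labels)
        mean_contrast = table.groupby(["cluster_a", "cluster_b"])[
            "abs_delta_beta"
        ].mean()
        assert mean_contrast.loc[(1, 3)] == mean_contrast.max()

    def test_fdr_within_each_cluster_pair(self, scores_and_labels):
        scores, labels = scores_and_labels
        table = im.delta_beta_contrasts(scores, labels)
        for _, grp in table.groupby(["cluster_a", "cluster_b"]):
            assert grp["dunn_fdr"].to_numpy() == pytest.approx(
                bh_fdr(grp["dunn_p"]), abs=1e-12
            )

    def test_fdr_invariant_to_row_order(self, scores_and_labels):
        scores, labels = scores_and_labels
        shuffled = ScoreMatrix(
            values=scores.values.sample(frac=1.0, random_state=3),
            modality="methylation",
        )
        a = im.delta_beta_contrasts(scores, labels)
        b = im.delta_beta_contrasts(shuffled, labels.sample(frac=1.0, random_state=4))
        key = ["cell_type", "cluster_a", "cluster_b"]
        merged = a.merge(b, on=key, suffixes=("_a", "_b"))
        assert merged["dunn_fdr_a"].to_numpy() == pytest.approx(
            merged["dunn_fdr_b"].to_numpy(), abs=1e-12
        )

    def test_null_scores_rarely_significant(self, rng):
        """Identical score distributions in every cluster: after the
        per-comparison BH correction across cell types, few entries
        reach FDR < 0.05."""
        flagged = []
        for _ in range(50):
            values = pd.DataFrame(
                rng.uniform(size=(60, 10)),
                index=[f"s{i}" for i in range(60)],
                columns=[f"ct{j}" for j in range(10)],
            )
            labels = pd.Series(
                rng.choice([1, 2, 3], size=60), index=values.index
            )
            if labels.value_counts().min() < 3:
                continue
            table = im.delta_beta_contrasts(
                ScoreMatrix(values=values, modality="methylation"), labels
            )
            flagged.append((table["dunn_fdr"] < 0.05).mean())
        assert np.mean(flagged) <= 0.10

    def test_small_cluster_excluded_with_warning(self, scores_and_labels):
        scores, labels = scores_and_labels
        labels = labels.copy()
        labels.iloc[:] = np.where(labels == 3, 3, labels)
        labels.iloc[:2] = 99  # a 2-sample pseudo-cluster
        with pytest.warns(UserWarning, match="excluding clusters"):
            table = im.delta_beta_contrasts(scores, labels)
        assert 99 not in set(table["cluster_a"]) | set(table["cluster_b"])


class TestCategoricalAssociation:
    def test_diagonal_two_by_two_fisher(self):
        labels = pd.Series([1] * 10 + [2] * 10, index=range(20))
        anno = pd.Series(["x"] * 10 + ["y"] * 10, index=range(20))
        res = im.categorical_association(labels, anno)
        assert res.method == "fisher"
        # only the two diagonal extremes are as extreme: p = 2 / C(20,10)
        assert res.p == pytest.approx(2 / 184756, rel=1e-9)

    def test_perfect_independence_p_one(self):
        labels = pd.Series([1] * 10 + [2] * 10, index=range(20))
        anno = pd.Series((["x"] * 5 + ["y"] * 5) * 2, index=range(20))
        res = im.categorical_association(labels, anno)
        assert res.p == pytest.approx(1.0)

    def test_null_pvalues_uniform(self, rng):
        pvals = []
        for _ in range(500):
            labels = pd.Series(rng.choice([1, 2, 3], size=200), index=range(200))
            anno = pd.Series(rng.choice(["a", "b", "c"], size=200), index=range(200))
            pvals.append(im.categorical_association(labels, anno).p)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_sparse_table_uses_monte_carlo(self, rng):
        labels = pd.Series([1] * 6 + [2] * 6 + [3] * 6, index=range(18))
        anno = pd.Series(
            ["a", "a", "b", "b", "c", "c"] * 3, index=range(18)
        )
        res = im.categorical_association(labels, anno, seed=1)
        assert res.method == "chi2-mc"
        assert 0.0 < res.p <= 1.0

    def test_degenerate_annotation_rejected(self):
        labels = pd.Series([1, 2, 1, 2], index=range(4))
        anno = pd.Series(["x", "x", "x", "x"], index=range(4))
        with pytest.raises(ValueError, match="degenerate"):
            im.categorical_association(labels, anno)

    def test_batched_fdr_across_annotations(self, cohort):
        out = im.association_batch(
            cohort.truth.sample_cluster_labels,
            cohort.clinical[["til_category", "mitf_status"]],
        )
        assert set(out["annotation"]) == {"til_category", "mitf_status"}
        assert (out["fdr"] >= out["p"] - 1e-12).all()


class TestSurvival:
    def test_identical_groups_give_null_hr(self, rng):
        base = pd.DataFrame(
            {
                "time": rng.exponential(5.0, size=80),
                "event": rng.integers(0, 2, size=80),
            },
            index=[f"s{i}" for i in range(80)],
        )
        doubled = pd.concat(
            [base, base.set_index(base.index + "_b")], axis=0
        )
        groups = pd.Series(
            ["A"] * 80 + ["B"] * 80, index=doubled.index
        )
        fit = im.fit_survival(doubled, groups, endpoint="OS")
        assert fit.iloc[0]["hr"] == pytest.approx(1.0, abs=1e-6)
        assert fit.iloc[0]["p"] > 0.99

    def test_zero_event_group_flagged_not_raised(self):
        clin = pd.DataFrame(
            {
                "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "event": [1, 1, 1, 0, 0, 0],
            },
            index=[f"s{i}" for i in range(6)],
        )
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=clin.index)
        fit = im.fit_survival(clin, groups, endpoint="OS")
        assert len(fit) == 1
        assert not fit.iloc[0]["estimable"]
        assert np.isnan(fit.iloc[0]["hr"])

    def test_hazard_ratio_recovery_and_events_ratio_agreement(self):
        df = im.simulate_two_group_survival(1000, 2.0, seed=42)
        fit = im.fit_survival(
            df.set_index(pd.Index([f"s{i}" for i in range(len(df))])),
            pd.Series(
                df["group"].to_numpy(),
                index=[f"s{i}" for i in range(len(df))],
            ),
            endpoint="OS",
        )
        hr = fit.iloc[0]["hr"]
        # closed-form exponential estimator: events / person-time per arm
        a = df[df["group"] == "A"]
        b = df[df["group"] == "B"]
        rate_ratio = (b["event"].sum() / b["time"].sum()) / (
            a["event"].sum() / a["time"].sum()
        )
        assert np.log(hr) == pytest.approx(np.log(rate_ratio), abs=0.05)
        assert fit.iloc[0]["ci_low"] <= hr <= fit.iloc[0]["ci_high"]

    def test_multivariate_adjustment_keeps_group_terms(self, cohort, consensus):
        fit = im.fit_survival(
            cohort.clinical,
            consensus.labels,
            covariates=["age", "sex"],
            endpoint="DMFS",
        )
        group_terms = fit[fit["term"].str.startswith("group[")]
        assert len(group_terms) == 2
        assert (group_terms["model"] == "multivariate").all()
        assert (fit["ci_low"] <= fit["hr"]).all()
        assert (fit["hr"] <= fit["ci_high"]).all()

    def test_reference_level_override(self):
        df = im.simulate_two_group_survival(400, 2.0, seed=9)
        idx = pd.Index([f"s{i}" for i in range(len(df))])
        clin = df.set_index(idx)
        groups = pd.Series(df["group"].to_numpy(), index=idx)
        forward = im.fit_survival(clin, groups, endpoint="OS")
        flipped = im.fit_survival(clin, groups, endpoint="OS", reference="B")
        assert forward.iloc[0]["hr"] == pytest.approx(
            1.0 / flipped.iloc[0]["hr"], rel=1e-6
        )

    def test_celltype_screen_shapes_and_flags(self, cohort, selected_pairs):
        pairs, _ = selected_pairs
        scores = im.methylation_score(cohort.beta, pairs)
        screen = im.cox_screen(
            im.dichotomize_score(scores), cohort.clinical, endpoint="DSS"
        )
        assert set(screen.index) == set(scores.values.columns)
        estimable = screen[screen["estimable"]]
        assert (estimable["hr_size"].isin(["large", "small"])).all()
        non_est = screen[~screen["estimable"]]
        assert non_est["hr"].isna().all()


class TestKaplanMeier:
    def test_single_group_no_test(self, cohort):
        labels = pd.Series("all", index=cohort.clinical.index)
        km = im.km_logrank(cohort.clinical, labels)
        assert km.logrank_p is None
        assert list(km.curves) == ["all"]

    def test_identical_groups_logrank_near_one(self, rng):
        clin = pd.DataFrame(
            {
                "time": np.tile(rng.exponential(5.0, size=100), 2),
                "event": np.tile(rng.integers(0, 2, size=100), 2),
            },
            index=[f"s{i}" for i in range(200)],
        )
        groups = pd.Series(["A"] * 100 + ["B"] * 100, index=clin.index)
        km = im.km_logrank(clin, groups)
        assert km.logrank_p > 0.95

    def test_strong_effect_detected(self):
        df = im.simulate_two_group_survival(400, 3.0, seed=3)
        idx = pd.Index([f"s{i}" for i in range(len(df))])
        km = im.km_logrank(
            df.set_index(idx), pd.Series(df["group"].to_numpy(), index=idx)
        )
        assert km.logrank_p < 0.001

    def test_display_horizon_truncates_curves_not_test(self, cohort, consensus):
        km = im.km_logrank(cohort.clinical, consensus.labels)
        for curve in km.curves.values():
            assert curve["timeline"].max() <= 10.0
        assert km.at_risk.shape[1] == 6  # horizons 0..10 by 2 years
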