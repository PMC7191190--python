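"""Signature combination, promoter mapping, and the CpG selection funnel."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import immunometh as im
from immunometh.selection import SelectionParams


def _sig(rows):
    return pd.DataFrame(rows, columns=["gene", "cell_type"])


class TestCombineSignatures:
    def test_conflicting_gene_removed(self):
        combined, report = im.combine_signatures(
            _sig([("G", "NK cells"), ("H", "Tregs")]),
            _sig([("G", "B cells")]),
        )
        assert "G" not in combined["gene"].values
        assert report["n_conflicts_removed"] == 1

    def test_single_source_gene_kept_with_its_type(self):
        combined, _ = im.combine_signatures(
            _sig([("H", "Tregs")]), _sig([("K", "Monocytes")])
        )
        assert dict(zip(combined["gene"], combined["cell_type"])) == {
            "H": "Tregs",
            "K": "Monocytes",
        }

    def test_agreeing_gene_deduplicated(self):
        combined, _ = im.combine_signatures(
            _sig([("K", "Monocytes")]), _sig([("K", "Monocytes")])
        )
        assert (combined["gene"] == "K").sum() == 1

    def test_empty_signature_rejected(self):
        with pytest.raises(ValueError):
            im.combine_signatures(_sig([]), _sig([("K", "Monocytes")]))

    def test_all_conflicts_is_an_error(self):
        with pytest.raises(ValueError, match="conflict"):
            im.combine_signatures(_sig([("G", "A")]), _sig([("G", "B")]))


class TestPromoterMapping:
    @pytest.fixture()
    def annotation(self):
        return pd.DataFrame(
            {
                "probe_id": ["cg1", "cg2", "cg3", "cg4"],
                "gene": ["G", "G", "G", "H"],
                "dist_to_tss_bp": [1500, 0, 100, -200],
                "platform_450k": [True, True, False, True],
                "platform_epic": [True, True, True, True],
            }
        )

    def test_boundary_distance_excluded_interior_included(self, annotation):
        sig = _sig([("G", "NK cells"), ("H", "B cells")])
        out = im.map_promoter_cpgs(sig, annotation)
        assert "cg1" not in out["probe_id"].values  # exactly 1500 bp: strict <
        assert "cg2" in out["probe_id"].values
        assert "cg4" in out["probe_id"].values  # negative distances: |.|

    def test_single_platform_probe_excluded(self, annotation):
        out = im.map_promoter_cpgs(_sig([("G", "NK cells")]), annotation)
        assert "cg3" not in out["probe_id"].values

    def test_missing_columns_rejected(self, annotation):
        with pytest.raises(ValueError, match="missing columns"):
            im.map_promoter_cpgs(
                _sig([("G", "NK cells")]), annotation.drop(columns=["platform_epic"])
            )


class TestBinarize:
    def test_threshold_semantics(self):
        beta = pd.DataFrame({"s": [0.29, 0.30, 0.0, np.nan]}, index=list("abcd"))
        out = im.binarize_beta(beta, 0.3)
        assert out.loc["a", "s"] == 0.0
        assert out.loc["b", "s"] == 1.0  # β = threshold counts methylated
        assert out.loc["c", "s"] == 0.0
        assert np.isnan(out.loc["d", "s"])

    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_binarization_matches_definition(self, value):
        beta = pd.DataFrame({"s": [value]}, index=["x"])
        out = im.binarize_beta(beta, 0.3)
        assert out.loc["x", "s"] == float(value >= 0.3)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            im.binarize_beta(pd.DataFrame({"s": [0.5]}), 1.5)


class TestNonimmuneFilter:
    def test_exact_fraction_fails_strictly(self):
        # 49/50 samples above 0.7 -> fraction 0.98, not > 0.98
        beta = pd.DataFrame([[0.9] * 49 + [0.5]], index=["cg1"])
        out = im.nonimmune_hypermethylation_filter(beta, SelectionParams())
        assert not out.loc["cg1"]

    def test_all_above_passes(self):
        beta = pd.DataFrame([[0.71] * 50], index=["cg1"])
        assert im.nonimmune_hypermethylation_filter(beta, SelectionParams()).loc["cg1"]

    def test_pancancer_boundary(self):
        params = SelectionParams.for_mode("pancancer")
        nine_of_ten = pd.DataFrame([[0.9] * 9 + [0.5]], index=["cg1"])
        ten_of_ten = pd.DataFrame([[0.9] * 10], index=["cg1"])
        assert not im.nonimmune_hypermethylation_filter(nine_of_ten, params).loc["cg1"]
        assert im.nonimmune_hypermethylation_filter(ten_of_ten, params).loc["cg1"]

    def test_beta_at_level_threshold_not_counted(self):
        beta = pd.DataFrame([[0.7] * 10], index=["cg1"])  # β > 0.7 is strict
        assert not im.nonimmune_hypermethylation_filter(beta, SelectionParams()).loc[
            "cg1"
        ]


class TestBestCpgPerGene:
    def _cands(self, rows):
        return pd.DataFrame(
            rows, columns=["gene", "probe_id", "cell_type", "p", "beta_range"]
        )

    def test_minimal_p_wins(self):
        out = im.select_best_cpg_per_gene(
            self._cands(
                [("G", "cg2", "T", 0.005, 0.5), ("G", "cg1", "T", 0.001, 0.5)]
            )
        )
        assert out["probe_id"].tolist() == ["cg1"]

    def test_tie_breaks_on_range_then_probe_id(self):
        out = im.select_best_cpg_per_gene(
            self._cands(
                [
                    ("G", "cg9", "T", 0.001, 0.9),
                    ("G", "cg1", "T", 0.001, 0.5),
                    ("H", "cg5", "T", 0.2, 0.1),
                    ("H", "cg4", "T", 0.2, 0.1),
                ]
            )
        )
        by_gene = out.set_index("gene")["probe_id"]
        assert by_gene["G"] == "cg9"  # larger range wins
        assert by_gene["H"] == "cg4"  # lexicographic fallback


class TestFisherDifferential:
    def test_missing_values_excluded_pairwise(self):
        types = pd.Series(["A"] * 3 + ["B"] * 3, index=[f"s{i}" for i in range(6)])
        binary = pd.DataFrame(
            [[0, 0, np.nan, 1, 1, 1]], index=["cg1"], columns=types.index
        )
        out = im.fisher_differential(binary, types)
        # table is [[2 unmeth, 0 meth], [0, 3]]; only the observed split is
        # as improbable -> p = 1/C(5,2) = 0.1
        assert out.loc["cg1", "p"] == pytest.approx(0.1)

    def test_mostly_missing_cpg_flagged(self):
        types = pd.Series(["A"] * 3 + ["B"] * 3, index=[f"s{i}" for i in range(6)])
        binary = pd.DataFrame(
            [[np.nan] * 4 + [1, 1], [0, 0, 0, 1, 1, 1]],
            index=["cg_bad", "cg_ok"],
            columns=types.index,
        )
        out = im.fisher_differential(binary, types)
        assert out.loc["cg_bad", "excluded_missing"]
        assert np.isnan(out.loc["cg_bad", "fdr"])
        assert not out.loc["cg_ok", "excluded_missing"]

    def test_requires_two_types_with_replicates(self):
        types = pd.Series(["A", "A", "A"], index=["s0", "s1", "s2"])
        binary = pd.DataFrame([[0, 1, 0]], index=["cg1"], columns=types.index)
        with pytest.raises(ValueError):
            im.fisher_differential(binary, types)

    def test_fdr_not_below_p(self, panel):
        types = panel.sample_types
        immune = types.index[~types.isin(["non_immune", "tumor_line"])]
        cpgs = list(panel.truth.marker_cpg_to_celltype)[:10]
        binary = im.binarize_beta(panel.beta.loc[cpgs, immune])
        out = im.fisher_differential(binary, types.loc[immune])
        assert (out["fdr"] >= out["p"] - 1e-12).all()


class TestRunSelection:
    def test_planted_markers_recovered_background_rejected(
        self, panel, selected_pairs
    ):
        pairs, report = selected_pairs
        truth = panel.truth.marker_cpg_to_celltype
        hits = sum(
            truth.get(row.probe_id) == row.cell_type
            for row in pairs.itertuples()
        )
        assert hits / len(truth) >= 0.9
        assert not set(pairs["probe_id"]) & set(panel.truth.background_cpgs)
        assert report["n_pairs"] == len(pairs)

    def test_confounder_cpgs_removed_by_stroma_filter(self, panel, selected_pairs):
        pairs, _ = selected_pairs
        assert not set(pairs["probe_id"]) & set(panel.truth.confounder_cpgs)

    def test_unique_genes_and_cpgs_and_filters_recheck(self, panel, selected_pairs):
        pairs, _ = selected_pairs
        assert pairs["gene"].is_unique and pairs["probe_id"].is_unique
        params = SelectionParams()
        nonimm_cols = panel.sample_types.index[
            panel.sample_types.isin(["non_immune", "tumor_line"])
        ]
        recheck = im.nonimmune_hypermethylation_filter(
            panel.beta.loc[pairs["probe_id"], nonimm_cols], params
        )
        assert recheck.all()
        assert (pairs["fdr"] < params.fdr_threshold).all()

    def test_label_permutation_kills_the_signal(self, panel, default_config):
        rng = np.random.default_rng(99)
        types = panel.sample_types.copy()
        immune_mask = ~types.isin(["non_immune", "tumor_line"])
        shuffled = types[immune_mask].sample(frac=1.0, random_state=7)
        types.loc[immune_mask] = shuffled.to_numpy()
        immune = types.index[immune_mask]
        cpgs = (
            list(panel.truth.marker_cpg_to_celltype)
            + panel.truth.background_cpgs[:200]
        )
        binary = im.binarize_beta(panel.beta.loc[cpgs, immune])
        out = im.fisher_differential(binary, types.loc[immune])
        frac_pass = (out["fdr"] < 0.01).mean()
        assert frac_pass <= 0.05

    def test_relaxing_stroma_fraction_never_shrinks_the_set(self, panel):
        strict, _ = im.run_selection(
            panel.beta, panel.sample_types, panel.signature_a, panel.signature_b,
            panel.annotation, SelectionParams.for_mode("melanoma"),
        )
        relaxed, _ = im.run_selection(
            panel.beta, panel.sample_types, panel.signature_a, panel.signature_b,
            panel.annotation, SelectionParams.for_mode("pancancer"),
        )
        assert set(strict["probe_id"]) <= set(relaxed["probe_id"])

    def test_best_cpg_chosen_among_multi_cpg_genes(self):
        cfg = im.SimulationConfig(seed=4, n_multi_cpg_genes=3)
        p = im.generate_reference_panel(cfg)
        pairs, _ = im.run_selection(
            p.beta, p.sample_types, p.signature_a, p.signature_b, p.annotation,
            SelectionParams(seed=4),
        )
        multi = pairs[pairs["gene"].str.startswith("MULTI")]
        assert multi["gene"].nunique() == len(multi)  # one CpG per gene
        assert len(multi) >= 2

    def test_empty_signature_errors(self, panel):
        empty = pd.DataFrame(columns=["gene", "cell_type"])
        with pytest.raises(ValueError):
            im.run_selection(
                panel.beta, panel.sample_types, empty, panel.signature_b,
                panel.annotation,
            )
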