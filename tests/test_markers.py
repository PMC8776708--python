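"""Marker statistics against enumeration oracles, signature scores and
dot-plot summaries against direct arithmetic, and the hypergeometric
over-representation test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dermalscore as ds
from dermalscore.markers import bh_adjust, rank_sum_test
from oracles import exact_ranksum_p, hypergeom_upper_p


class TestRankSum:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        n_x=st.integers(2, 6),
        n_y=st.integers(2, 6),
        seed=st.integers(0, 10_000),
    )
    def test_matches_exact_enumeration(self, n_x, n_y, seed):
        rng = np.random.default_rng(seed)
        vals = rng.permutation(np.arange(1.0, n_x + n_y + 1))  # tie-free
        x, y = vals[:n_x], vals[n_x:]
        for alt in ("two-sided", "greater"):
            _, p = rank_sum_test(x, y, alternative=alt)
            assert p == pytest.approx(exact_ranksum_p(x, y, alt), rel=1e-9)

    def test_identical_values_p_one(self):
        _, p = rank_sum_test(np.ones(5), np.ones(7))
        assert p == 1.0

    def test_complete_separation_one_sided_minimal_tail(self):
        # all of x above all of y: one-sided p = 1 / C(nx+ny, nx)
        x = np.arange(10.0, 14.0)
        y = np.arange(0.0, 5.0)
        _, p = rank_sum_test(x, y, alternative="greater")
        from math import comb
        assert p == pytest.approx(1 / comb(9, 4), rel=1e-9)


class TestFindMarkers:
    def test_planted_marker_significant(self, filtered_normalized):
        _, norm, meta = filtered_normalized
        table = ds.find_markers(norm, meta.cluster.to_numpy(), "F4a")
        ds_rows = table[table.gene.isin(ds.synthetic.DS_SIGNATURE)]
        assert len(ds_rows) == 10
        assert (ds_rows.p_adj < 0.05).all()
        assert (ds_rows.log_fc > 0).all()

    def test_small_group_matches_enumeration(self, make_matrix):
        rng = np.random.default_rng(1)
        counts = rng.permutation(np.arange(1, 41)).reshape(10, 4)
        # filler gene equalizes cell totals so per-gene values stay tie-free
        filler = 200 - counts.sum(axis=1)
        counts = np.column_stack([counts, filler])
        cm = make_matrix(counts)
        norm = ds.normalize(cm)
        labels = np.array(["A"] * 5 + ["B"] * 5)
        table = ds.find_markers(norm, labels, "A", min_pct=0).set_index("gene")
        dense = norm.values.toarray()
        for j, g in enumerate(cm.gene_symbols[:4]):
            expect = exact_ranksum_p(dense[:5, j], dense[5:, j])
            assert table.loc[g, "p"] == pytest.approx(expect, rel=1e-9)

    def test_logfc_sign_and_formula(self, make_matrix):
        counts = np.zeros((6, 2), dtype=int)
        counts[:, 1] = 5  # constant gene keeps totals equal
        counts[:3, 0] = 8
        cm = make_matrix(counts)
        norm = ds.normalize(cm)
        labels = np.array(["hi"] * 3 + ["lo"] * 3)
        row = ds.find_markers(norm, labels, "hi", min_pct=0).set_index("gene").loc["G0"]
        dense = np.expm1(norm.values.toarray())
        expect = np.log((dense[:3, 0].mean() + 1) / (dense[3:, 0].mean() + 1))
        assert row.log_fc == pytest.approx(expect, rel=1e-9)
        assert row.pct_in == 1.0 and row.pct_out == 0.0

    def test_absent_cluster_rejected(self, filtered_normalized):
        _, norm, meta = filtered_normalized
        with pytest.raises(ValueError):
            ds.find_markers(norm, meta.cluster.to_numpy(), "NOPE")

    def test_bonferroni_over_tested_genes(self, filtered_normalized):
        _, norm, meta = filtered_normalized
        table = ds.find_markers(norm, meta.cluster.to_numpy(), "F1")
        assert np.allclose(
            table.p_adj, np.minimum(table.p * len(table), 1.0), rtol=1e-12
        )


class TestSignatureScore:
    def test_single_gene_identity(self, filtered_normalized):
        _, norm, _ = filtered_normalized
        scores, missing = ds.signature_score(norm, ds.GeneSignature("s", ["SPARC"]))
        j = list(norm.gene_symbols).index("SPARC")
        assert np.allclose(scores, norm.values[:, j].toarray().ravel())
        assert missing == []

    def test_zero_cells_score_zero(self, make_matrix):
        cm = make_matrix(np.array([[0, 5], [3, 5]]), symbols=["SIG", "OTHER"])
        norm = ds.normalize(cm)
        scores, _ = ds.signature_score(norm, ds.GeneSignature("s", ["SIG"]))
        assert scores[0] == 0.0 and scores[1] > 0

    def test_order_invariant(self, filtered_normalized):
        _, norm, _ = filtered_normalized
        genes = list(ds.synthetic.DS_SIGNATURE)
        s1, _ = ds.signature_score(norm, ds.GeneSignature("a", genes))
        s2, _ = ds.signature_score(norm, ds.GeneSignature("b", genes[::-1]))
        assert np.allclose(s1, s2)

    def test_planted_program_ranks_f4a_highest(self, filtered_normalized):
        _, norm, meta = filtered_normalized
        scores, _ = ds.signature_score(
            norm, ds.GeneSignature("DS", list(ds.synthetic.DS_SIGNATURE))
        )
        means = pd.Series(scores).groupby(meta.cluster.to_numpy()).mean()
        assert means.idxmax() == "F4a"

    def test_all_missing_rejected(self, filtered_normalized):
        _, norm, _ = filtered_normalized
        with pytest.raises(ValueError):
            ds.signature_score(norm, ds.GeneSignature("s", ["NOT-A-GENE"]))


class TestDotplot:
    def test_toy_arithmetic(self, make_matrix):
        counts = np.array(
            [[2, 0, 5], [1, 0, 5], [0, 3, 5], [0, 1, 5], [4, 4, 5], [0, 0, 5]]
        )
        cm = make_matrix(counts, symbols=["A", "B", "C"])
        norm = ds.normalize(cm)
        labels = np.array(["x", "x", "y", "y", "z", "z"])
        dp = ds.dotplot_summary(norm, labels, genes=["A", "B"])
        dp = dp.set_index(["cluster", "feature"])
        dense = norm.values.toarray()
        assert dp.loc[("x", "A"), "pct_expressed"] == 100.0
        assert dp.loc[("x", "B"), "pct_expressed"] == 0.0
        assert dp.loc[("x", "B"), "avg_expression"] == 0.0
        assert dp.loc[("z", "A"), "pct_expressed"] == 50.0
        assert dp.loc[("y", "B"), "avg_expression"] == pytest.approx(
            dense[2:4, 1].mean()
        )

    def test_absent_gene_zero(self, make_matrix):
        cm = make_matrix(np.array([[1, 1], [2, 2]]))
        dp = ds.dotplot_summary(ds.normalize(cm), np.array(["a", "a"]), genes=["ZZZ"])
        assert (dp.pct_expressed == 0).all() and (dp.avg_expression == 0).all()


class TestEnrichment:
    def test_query_equals_term_enumeration(self):
        universe = [f"g{i}" for i in range(40)]
        term = universe[:8]
        p, fold = ds.enrichment_test(term, term, universe)
        assert p == pytest.approx(hypergeom_upper_p(8, 40, 8, 8), rel=1e-9)
        assert fold == pytest.approx((8 / 8) / (8 / 40))

    def test_disjoint_p_one(self):
        universe = [f"g{i}" for i in range(30)]
        p, fold = ds.enrichment_test(universe[:5], universe[10:15], universe)
        assert p == 1.0 and fold == 0.0

    def test_expected_overlap_fold_one(self):
        # |query|=10, |term|=10, universe=100 -> expected overlap 1
        universe = [f"g{i}" for i in range(100)]
        query = universe[:10]
        term = universe[9:19]  # overlap exactly 1
        _, fold = ds.enrichment_test(query, term, universe)
        assert fold == pytest.approx(1.0)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            ds.enrichment_test(["zz"], ["a"], ["a", "b"])

    def test_bh_adjustment_table(self):
        universe = [f"g{i}" for i in range(50)]
        terms = {"t1": universe[:10], "t2": universe[20:25], "t3": universe[30:45]}
        table = ds.enrichment_table(universe[:10], terms, universe)
        manual = bh_adjust(table.p.to_numpy())
        assert np.allclose(table.p_adj, manual)
        assert (table.p_adj >= table.p - 1e-15).all()


def test_bh_adjust_matches_statsmodels_convention():
    p = np.array([0.01, 0.02, 0.03, 0.5, 1.0])
    out = bh_adjust(p)
    # step-up: p_(i) * n/i with monotonicity from the top
    assert out == pytest.approx([0.05, 0.05, 0.05, 0.625, 1.0])
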