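"""2x2 composition tables, Fisher odds ratios against an enumeration
oracle, CI conventions, and per-donor fraction t-tests."""

import numpy as np
import pandas as pd
import pytest

import dermalscore as ds
from dermalscore.synthetic import simulate_membership_counts
from oracles import fisher_two_sided_p, pooled_t


def meta_from_counts(y_in, y_out, o_in, o_out):
    rows = (
        [("young", "X")] * y_in
        + [("young", "rest")] * y_out
        + [("old", "X")] * o_in
        + [("old", "rest")] * o_out
    )
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(len(rows))],
            "age_group": [r[0] for r in rows],
            "cluster": [r[1] for r in rows],
        }
    )


class TestCompositionTable:
    def test_direct_count(self):
        meta = meta_from_counts(2, 0, 0, 2)
        t = ds.composition_table(meta, "X")
        assert (t.a, t.b, t.c, t.d) == (0, 2, 2, 0)

    def test_partition_over_clusters(self, small_cohort):
        _, meta, _ = small_cohort
        total_in = sum(
            ds.composition_table(meta, cl).a + ds.composition_table(meta, cl).c
            for cl in meta.cluster.unique()
        )
        assert total_in == len(meta)

    def test_matches_ground_truth_tallies(self, small_cohort):
        _, meta, gt = small_cohort
        t = ds.composition_table(meta, "F4a")
        old = meta.age_group == "old"
        assert t.a == ((gt.cell_population.to_numpy() == "F4a") & old.to_numpy()).sum()

    def test_absent_cluster_rejected(self, small_cohort):
        _, meta, _ = small_cohort
        with pytest.raises(ValueError):
            ds.composition_table(meta, "F99")


class TestFisherOR:
    def test_cross_product_arithmetic(self):
        t = ds.ContingencyTable(10, 90, 5, 95)
        row = ds.fisher_or(t, "old-enriched")
        assert row["OR"] == pytest.approx((10 * 95) / (90 * 5), rel=1e-12)

    def test_homogeneous_table_or_one(self):
        t = ds.ContingencyTable(20, 40, 10, 20)
        row = ds.fisher_or(t)
        assert row["OR"] == pytest.approx(1.0)
        assert row["p"] == pytest.approx(1.0, abs=1e-9)

    def test_p_matches_enumeration_exhaustive_small(self):
        """Two-sided p equals the hypergeometric-support scan for every
        table with all cells in 1..6."""
        for a in range(1, 7):
            for b in range(1, 7):
                for c in range(1, 7):
                    for d in range(1, 7):
                        row = ds.fisher_or(ds.ContingencyTable(a, b, c, d))
                        expect = fisher_two_sided_p(a, b, c, d)
                        assert row["p"] == pytest.approx(expect, rel=1e-9), (a, b, c, d)

    def test_p_matches_enumeration_sampled_to_60(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(8, 61))
            cells = rng.multinomial(n, [0.25] * 4) + 0
            a, b, c, d = (int(x) for x in cells)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            row = ds.fisher_or(ds.ContingencyTable(a, b, c, d))
            assert row["p"] == pytest.approx(
                fisher_two_sided_p(a, b, c, d), rel=1e-9
            )

    def test_orientation_reciprocal(self):
        t = ds.ContingencyTable(10, 90, 5, 95)
        old = ds.fisher_or(t, "old-enriched")
        young = ds.fisher_or(t, "young-enriched")
        assert young["OR"] == pytest.approx(1 / old["OR"], rel=1e-12)
        assert young["p"] == old["p"]

    def test_row_swap_inverts_or_keeps_p(self):
        t1 = ds.ContingencyTable(7, 23, 11, 19)
        t2 = ds.ContingencyTable(11, 19, 7, 23)
        r1, r2 = ds.fisher_or(t1), ds.fisher_or(t2)
        assert r2["OR"] == pytest.approx(1 / r1["OR"], rel=1e-12)
        assert r2["p"] == pytest.approx(r1["p"], rel=1e-12)

    def test_double_swap_invariant(self):
        t1 = ds.ContingencyTable(7, 23, 11, 19)
        t2 = ds.ContingencyTable(19, 11, 23, 7)  # rows and columns swapped
        r1, r2 = ds.fisher_or(t1), ds.fisher_or(t2)
        assert r2["OR"] == pytest.approx(r1["OR"], rel=1e-12)
        assert r2["p"] == pytest.approx(r1["p"], rel=1e-12)

    def test_woolf_ci_brackets_or(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 40, size=4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            row = ds.fisher_or(ds.ContingencyTable(int(a), int(b), int(c), int(d)))
            assert row["ci_low"] <= row["OR"] <= row["ci_high"]

    def test_woolf_formula_direct(self):
        t = ds.ContingencyTable(12, 34, 9, 41)
        row = ds.fisher_or(t)
        se = np.sqrt(1 / 12 + 1 / 34 + 1 / 9 + 1 / 41)
        lo = np.exp(np.log(row["OR"]) - 1.959963984540054 * se)
        assert row["ci_low"] == pytest.approx(lo, rel=1e-12)

    def test_haldane_applied_iff_zero_cell(self):
        row = ds.fisher_or(ds.ContingencyTable(0, 20, 5, 15))
        assert row["haldane"]
        assert np.isfinite(row["OR"]) and row["OR"] > 0
        assert not ds.fisher_or(ds.ContingencyTable(1, 20, 5, 15))["haldane"]

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            ds.fisher_or(ds.ContingencyTable(0, 0, 5, 15))


class TestORRecovery:
    def test_generating_or_recovered(self):
        """Mean estimated OR over replicate cohorts approaches the odds
        ratio implied by the membership probabilities."""
        rng = np.random.default_rng(123)
        true_or = (0.034 / 0.966) / (0.004935 / 0.995065)
        ors = []
        for _ in range(50):
            y_in, y_out, o_in, o_out = simulate_membership_counts(
                19139, 31010, 0.034, 0.004935, rng
            )
            t = ds.ContingencyTable(o_in, o_out, y_in, y_out)
            ors.append(ds.fisher_or(t, "young-enriched")["OR"])
        assert np.mean(ors) == pytest.approx(true_or, rel=0.05)


class TestFractionTest:
    def test_identical_fractions_null(self):
        res = ds.fraction_test(
            np.array([0.1, 0.1, 0.1, 0.1]), np.array(["young"] * 2 + ["old"] * 2)
        )
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_matches_pooled_formula(self):
        x = np.array([0.12, 0.08, 0.10])
        y = np.array([0.03, 0.05, 0.02])
        res = ds.fraction_test(
            np.concatenate([x, y]), np.array(["young"] * 3 + ["old"] * 3)
        )
        assert res["t"] == pytest.approx(pooled_t(x, y), rel=1e-9)
        assert res["mean_a"] == pytest.approx(x.mean())

    def test_single_donor_group_rejected(self):
        with pytest.raises(ValueError):
            ds.fraction_test(np.array([0.1, 0.2]), np.array(["young", "old"]))

    def test_power_at_study_donor_numbers(self):
        """With a 7-fold DS depletion planted in old donors and the 8 young /
        9 old donor design, the t-test detects the shift in >= 90% of
        replicates."""
        rng = np.random.default_rng(2024)
        cells = 2000
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            young = rng.binomial(cells, 0.034, size=8) / cells
            old = rng.binomial(cells, 0.004935, size=9) / cells
            res = ds.fraction_test(
                np.concatenate([young, old]),
                np.array(["young"] * 8 + ["old"] * 9),
            )
            hits += res["p"] < 0.05
        assert hits >= 90


def test_donor_fractions_and_analysis(small_cohort):
    _, meta, _ = small_cohort
    fr = ds.donor_fractions(meta, "F1")
    assert len(fr) == 7
    manual = (meta[meta.donor == "Y1"].cluster == "F1").mean()
    assert fr.loc["Y1", "fraction"] == pytest.approx(manual)
    comp = ds.composition_analysis(meta)
    assert set(comp.cluster) == set(meta.cluster.unique())
    assert ((comp.ci_low <= comp.OR) & (comp.OR <= comp.ci_high)).all()
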