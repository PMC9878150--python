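import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tebias.stats import (MorphismNullModel, bh_adjust,
                          conditional_morphism_probabilities,
                          expected_morphism_counts, goodness_of_fit,
                          independence_test, morphism_gof, morphism_report,
                          screen_te_groups, single_gene_te_probability)


def enumerate_conditional(p, k):
    """Brute-force oracle: enumerate all 2^k presence patterns."""
    mono = poly = any_te = 0.0
    for pattern in itertools.product([0, 1], repeat=k):
        j = sum(pattern)
        w = p ** j * (1 - p) ** (k - j)
        if j >= 1:
            any_te += w
            if j == k:
                mono += w
            else:
                poly += w
    return mono / any_te, poly / any_te


class TestSingleGeneProbability:
    def test_printed_dyad_counts(self):
        # 1,312 polymorphic dyads (1 TE gene each) + 1,074 monomorphic (2 each)
        counts = [1] * 1312 + [2] * 1074
        p = single_gene_te_probability(counts, 2)
        assert p == pytest.approx(3460 / 4772)
        assert p == pytest.approx(0.72506, abs=5e-6)

    def test_all_monomorphic_gives_one(self):
        assert single_gene_te_probability([3, 3, 3], 3) == 1.0

    def test_hand_count_k3(self):
        assert single_gene_te_probability([1, 2, 3, 2], 3) == 8 / 12

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            single_gene_te_probability([], 2)

    def test_out_of_range_count_raises(self):
        with pytest.raises(ValueError):
            single_gene_te_probability([0, 2], 2)


class TestConditionalProbabilities:
    def test_dyad_printed_value(self):
        p = 3460 / 4772
        _, p_poly = conditional_morphism_probabilities(p, 2)
        assert round(100 * p_poly, 2) == 43.13

    def test_p_one_never_polymorphic(self):
        for k in (2, 3, 4):
            p_mono, p_poly = conditional_morphism_probabilities(1.0, k)
            assert p_poly == 0.0
            assert p_mono == 1.0

    def test_half_k2_closed_form(self):
        _, p_poly = conditional_morphism_probabilities(0.5, 2)
        assert p_poly == pytest.approx(2 / 3)

    def test_p_zero_rejected(self):
        with pytest.raises(ValueError):
            conditional_morphism_probabilities(0.0, 2)

    @pytest.mark.parametrize("k", [2, 3, 4])
    @pytest.mark.parametrize("p", np.linspace(0.05, 0.95, 10).tolist())
    def test_matches_enumeration(self, p, k):
        mono, poly = conditional_morphism_probabilities(p, k)
        e_mono, e_poly = enumerate_conditional(p, k)
        assert abs(mono - e_mono) < 1e-12
        assert abs(poly - e_poly) < 1e-12
        assert mono + poly == pytest.approx(1.0)


class TestExpectedCounts:
    def test_dyad_model_expectations(self):
        model = MorphismNullModel.from_counts(1312, 1074, 2)
        mono, poly = expected_morphism_counts(model)
        assert poly == pytest.approx(1029.1, abs=0.1)
        assert mono == pytest.approx(1356.9, abs=0.1)

    def test_p_one_no_polymorphic(self):
        model = MorphismNullModel.fit([2, 2, 2], 2)
        assert model.expected_polymorphic == 0.0

    def test_expectations_sum_to_n(self):
        model = MorphismNullModel.from_counts(321, 67, 4, te_gene_total=900)
        total = model.expected_monomorphic + model.expected_polymorphic
        assert total == pytest.approx(model.n_groups, abs=1e-6)

    def test_from_counts_needs_total_for_k3(self):
        with pytest.raises(ValueError):
            MorphismNullModel.from_counts(10, 5, 3)


class TestGoodnessOfFit:
    def test_printed_dyad_gof(self):
        model = MorphismNullModel.from_counts(1312, 1074, 2)
        chi2, p = morphism_gof(1312, 1074, model)
        assert round(chi2, 2) == 136.78
        assert p < 0.001

    def test_perfect_fit(self):
        chi2, p = goodness_of_fit([5, 5], [5, 5])
        assert chi2 == 0.0
        assert p == pytest.approx(1.0)

    def test_toy_hand_arithmetic(self):
        chi2, _ = goodness_of_fit([10, 0], [5, 5])
        assert chi2 == pytest.approx(10.0)

    def test_nonpositive_expected_rejected(self):
        with pytest.raises(ValueError):
            goodness_of_fit([1, 2], [0, 3])


class TestIndependenceTest:
    def test_printed_dyad_polymorphism_expression(self):
        chi2, _ = independence_test([[497, 815], [335, 739]])
        assert round(chi2, 2) == 11.34

    def test_printed_2x3_te_content(self):
        table = [[3972, 20975, 864], [8668, 34195, 2144]]
        chi2, p = independence_test(table)
        assert round(chi2, 2) == 273.99
        assert p < 0.001

    def test_proportional_rows_give_zero(self):
        chi2, p = independence_test([[10, 20], [30, 60]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            independence_test([[0, 0], [3, 4]])

    @given(st.tuples(*[st.integers(1, 200)] * 4))
    def test_yates_hand_formula(self, cells):
        a, b, c, d = cells
        n = a + b + c + d
        corrected = n * max(abs(a * d - b * c) - n / 2, 0) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d))
        chi2, _ = independence_test([[a, b], [c, d]])
        assert chi2 == pytest.approx(corrected, rel=1e-9, abs=1e-9)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_monotone_and_bounded(self, ps):
        qs = bh_adjust(ps)
        assert np.all(qs >= np.asarray(ps) - 1e-12)
        assert np.all(qs <= 1.0)
        order = np.argsort(ps)
        assert np.all(np.diff(qs[order]) >= -1e-12)


class TestScreen:
    @pytest.fixture
    def screen_data(self):
        rng = np.random.default_rng(0)
        n = 400
        idx = pd.Index([f"t{i}" for i in range(n)], name="group_id")
        cats = pd.Series(
            rng.choice(["balanced", "A_suppressed", "B_dominant"], n,
                       p=[0.7, 0.2, 0.1]), index=idx)
        presence = pd.DataFrame(
            {"DTT": rng.random(n) < 0.5,
             "RLC": rng.random(n) < 0.3,
             "DTA": rng.random(n) < 0.01},
            index=idx)
        return presence, cats

    def test_min_cell_filter(self, screen_data):
        presence, cats = screen_data
        res = screen_te_groups(presence, cats, "balanced_vs_nonbalanced")
        res = res.set_index("te_group")
        assert not res.loc["DTA", "included"]
        assert res.loc["DTT", "included"]
        assert np.isnan(res.loc["DTA", "q"]) or res.loc["DTA", "q"] is None

    def test_cells_reconstruct_totals(self, screen_data):
        presence, cats = screen_data
        res = screen_te_groups(presence, cats, "suppressed_vs_notsuppressed")
        cells = res[["present_in", "present_out", "absent_in", "absent_out"]]
        assert (cells.sum(axis=1) == len(presence)).all()

    def test_q_at_least_p(self, screen_data):
        presence, cats = screen_data
        res = screen_te_groups(presence, cats, "balanced_vs_nonbalanced")
        ok = res[res["included"]]
        assert (ok["q"] >= ok["p_raw"] - 1e-12).all()

    def test_order_invariance(self, screen_data):
        presence, cats = screen_data
        res1 = screen_te_groups(presence, cats, "balanced_vs_nonbalanced")
        shuffled = presence.sample(frac=1, random_state=7)
        res2 = screen_te_groups(shuffled, cats.loc[shuffled.index],
                                "balanced_vs_nonbalanced")
        merged = res1.merge(res2, on="te_group", suffixes=("_a", "_b"))
        assert (merged["chi2_a"].fillna(-1) == merged["chi2_b"].fillna(-1)).all()

    def test_direction_negative_example(self):
        # observed present&balanced below independence expectation
        idx = pd.Index(range(1132 + 5252 + 227 + 828))
        cats = pd.Series(["balanced"] * 1132 + ["balanced"] * 5252
                         + ["A_suppressed"] * 227 + ["A_suppressed"] * 828,
                         index=idx)
        pres = pd.Series([True] * 1132 + [False] * 5252
                         + [True] * 227 + [False] * 828, index=idx)
        res = screen_te_groups(pd.DataFrame({"RLC": pres}), cats,
                               "balanced_vs_nonbalanced")
        row = res.iloc[0]
        assert (row.present_in, row.present_out,
                row.absent_in, row.absent_out) == (1132, 227, 5252, 828)
        assert row.direction == "negative"

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            screen_te_groups(pd.DataFrame(), pd.Series(dtype=object),
                             "balanced_vs_nonbalanced")

    def test_unknown_comparison_raises(self, screen_data):
        presence, cats = screen_data
        with pytest.raises(ValueError):
            screen_te_groups(presence, cats, "weird")


class TestMorphismReport:
    def test_small_hand_tally(self):
        df = pd.DataFrame({
            "group_id": ["a", "b", "c", "d"],
            "cardinality": [2, 2, 2, 2],
            "morphism": ["polymorphic", "monomorphic", "polymorphic", "no_te"],
            "region_status": ["proximal"] * 4,
        })
        counts = {"a": 1, "b": 2, "c": 1, "d": 0}
        rep = morphism_report(df, counts, stratify_region=False)
        row = rep.iloc[0]
        assert row["n_te_groups"] == 3
        assert row["observed_poly"] == 2
        assert row["p_single_gene"] == pytest.approx(4 / 6)
        total = row["expected_poly"] + row["expected_mono"]
        assert total == pytest.approx(3.0, abs=1e-9)
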