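"""Quantile normalization, ratio summaries with notch CIs, and sex-bias
classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import karyoshift as ks
from karyoshift.dosage import (
    _notch_summary,
    classify_mf_bias,
    classify_testis_bias,
    compare_bias_proportions,
    current_ancestral_analysis,
    mf_ratio_analysis,
    pairwise_expression_filter,
    quantile_normalize,
)


class TestQuantileNormalize:
    def test_hand_example(self):
        qa, qb = quantile_normalize(np.array([1.0, 2, 3]), np.array([2.0, 4, 6]))
        assert np.array_equal(qa, [1.5, 3.0, 4.5])
        assert np.array_equal(qb, [1.5, 3.0, 4.5])

    def test_fixed_point_when_inputs_equal(self):
        a = np.array([5.0, 1.0, 3.0])
        qa, qb = quantile_normalize(a, a.copy())
        assert np.array_equal(qa, a)
        assert np.array_equal(qb, a)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        a, b = rng.lognormal(1, 1, 50), rng.lognormal(2, 0.5, 50)
        qa, qb = quantile_normalize(a, b)
        qa2, qb2 = quantile_normalize(qa, qb)
        assert np.allclose(qa, qa2) and np.allclose(qb, qb2)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=0.01, max_value=1e4), min_size=2, max_size=30, unique=True
        ).flatmap(
            lambda a: st.tuples(
                st.just(a),
                st.lists(
                    st.floats(min_value=0.01, max_value=1e4),
                    min_size=len(a), max_size=len(a), unique=True,
                ),
            )
        )
    )
    def test_output_multisets_identical_and_mean_conserved(self, ab):
        a, b = map(np.asarray, ab)
        qa, qb = quantile_normalize(a, b)
        assert np.allclose(np.sort(qa), np.sort(qb))  # identical distributions
        assert np.isclose(qa.mean() + qb.mean(), a.mean() + b.mean())  # pooled mean

    def test_ties_preserve_pooled_mean(self):
        a = np.array([1.0, 1.0, 4.0])
        b = np.array([2.0, 3.0, 9.0])
        qa, qb = quantile_normalize(a, b)
        assert qa[0] == qa[1]  # tied inputs get identical outputs
        assert np.isclose(qa.sum() + qb.sum(), a.sum() + b.sum())


class TestFilterAndNotch:
    def test_filter_drops_only_when_low_in_both(self):
        a = np.array([0.99, 0.99, 1.0, 5.0])
        b = np.array([0.99, 2.00, 0.5, 5.0])
        assert list(pairwise_expression_filter(a, b)) == [False, True, True, True]

    def test_notch_ci_formula(self):
        # values 1..9: median 5, IQR 4 (type-7 quartiles), n=9
        s = _notch_summary(np.arange(1.0, 10.0), "X", np.nan)
        assert s.median_log2_ratio == 5.0
        assert s.ci_half_width == pytest.approx(1.57 * 4 / 3)


class TestRatioAnalyses:
    def test_equal_samples_are_null(self):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(3, 1, 300)
        is_x = np.arange(300) < 60
        summaries, per_gene = mf_ratio_analysis(vals, vals.copy(), is_x)
        by = {s.chromosome_class: s for s in summaries}
        assert by["X"].median_log2_ratio == pytest.approx(0.0, abs=1e-12)
        assert by["X"].rank_test_p > 0.5
        assert (per_gene["log2_ratio"] == 0).all()

    def test_uncompensated_x_centres_at_half(self):
        rng = np.random.default_rng(2)
        f = rng.lognormal(3, 1, 500)
        is_x = np.arange(500) < 100
        m = f * np.where(is_x, 0.5, 1.0)
        summaries, _ = mf_ratio_analysis(m, f, is_x)
        by = {s.chromosome_class: s for s in summaries}
        assert by["autosome"].median_log2_ratio == pytest.approx(0.0, abs=1e-12)
        assert by["X"].median_log2_ratio == pytest.approx(-1.0, abs=0.15)
        assert by["X"].rank_test_p < 1e-10

    def test_autosomal_median_exactly_one_after_recentring(self):
        rng = np.random.default_rng(3)
        m = rng.lognormal(3, 1, 201)
        f = rng.lognormal(3.2, 0.8, 201)  # global scale offset
        is_x = np.arange(201) < 40
        summaries, _ = mf_ratio_analysis(m, f, is_x)
        auto = [s for s in summaries if s.chromosome_class == "autosome"][0]
        assert auto.median_log2_ratio == pytest.approx(0.0, abs=1e-12)

    def test_global_scale_invariance(self):
        # quantile normalization removes a global scale: the rank test is
        # exactly invariant, the recentred medians nearly so
        rng = np.random.default_rng(4)
        m = rng.lognormal(3, 1, 150)
        f = rng.lognormal(3, 1, 150)
        is_x = np.arange(150) < 30
        base, _ = mf_ratio_analysis(m, f, is_x)
        scaled, _ = mf_ratio_analysis(m * 7.3, f, is_x)
        # QN preserves ranks within samples but not per-gene ratios exactly,
        # so statistics agree closely and the calls agree exactly
        for s0, s1 in zip(base, scaled):
            assert s0.median_log2_ratio == pytest.approx(s1.median_log2_ratio, abs=0.05)
            if not np.isnan(s0.rank_test_p):
                assert s0.rank_test_p == pytest.approx(s1.rank_test_p, abs=0.1)
                assert (s0.rank_test_p < 0.05) == (s1.rank_test_p < 0.05)

    def test_current_ancestral_identity(self):
        rng = np.random.default_rng(5)
        vals = rng.lognormal(3, 1, 120)
        pairs = pd.DataFrame(
            {
                "current_male": vals, "ancestral_male": vals.copy(),
                "current_female": vals, "ancestral_female": vals.copy(),
                "is_x": np.arange(120) < 30,
            }
        )
        for sex in ("male", "female"):
            summaries, _ = current_ancestral_analysis(pairs, sex)
            for s in summaries:
                assert s.median_ratio == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize(
        "mode, expected_male_x, expected_female_x",
        [("male_up", 1.0, 1.0), ("none", 0.5, 1.0), ("female_down", 0.5, 0.5)],
    )
    def test_compensation_mode_recovery(self, mode, expected_male_x, expected_female_x):
        cfg = ks.ScenarioConfig(
            per_element_scenario={"D": ks.ElementScenario("diff_X")},
            compensation_mode=mode, seed=37,
        )
        scaffolds, truth = ks.simulate_genome(cfg)
        ks.simulate_gene_hits(scaffolds, truth, cfg)
        expr, anc, orth = ks.simulate_expression(truth, cfg)
        from karyoshift.dosage import build_ortholog_pairs

        pairs = build_ortholog_pairs(expr, anc, orth, "whole_body", ["D"])
        for sex, expected in (("male", expected_male_x), ("female", expected_female_x)):
            summaries, _ = current_ancestral_analysis(pairs, sex)
            x = [s for s in summaries if s.chromosome_class == "X"][0]
            lo, hi = x.ci_ratio()
            assert lo < expected < hi or abs(x.median_ratio - expected) < 0.1


class TestSexBias:
    @pytest.mark.parametrize(
        "testis, others, expected",
        [
            (30.0, 9.0, "strongly_testis_biased"),  # ratio 3.33
            (27.0, 9.0, "strongly_testis_biased"),  # exactly 3-fold (>= convention)
            (100.0, 10.0, "testis_specific"),  # exactly 10-fold
            (29.0, 10.0, "none"),  # below 3-fold
            (90.0, 10.0, "strongly_testis_biased"),  # 9-fold: strong, not specific
        ],
    )
    def test_testis_rules(self, testis, others, expected):
        samples = pd.DataFrame(
            {"testis": [testis], "male_head": [others], "female_head": [others * 0.9],
             "female_body": [others * 0.8], "ovary": [others * 0.7]}
        )
        assert classify_testis_bias(samples)[0] == expected

    def test_specific_implies_strong_criteria(self):
        rng = np.random.default_rng(6)
        samples = pd.DataFrame(
            {c: rng.lognormal(2, 1.5, 300) for c in
             ("testis", "male_head", "female_head", "female_body", "ovary")}
        )
        cats = classify_testis_bias(samples)
        specific = samples[cats == "testis_specific"]
        if len(specific):
            max_other = specific[["male_head", "female_head", "female_body", "ovary"]].max(axis=1)
            assert (specific["testis"] >= 3 * max_other).all()

    def test_missing_samples_raise(self):
        with pytest.raises(ValueError, match="ovary"):
            classify_testis_bias(pd.DataFrame({"testis": [1.0], "male_head": [1.0]}))

    @pytest.mark.parametrize(
        "m, f, expected",
        [
            (10.0, 10.0, "unbiased"),
            (25.0, 10.0, "male_biased"),
            (60.0, 10.0, "strongly_male"),
            (10.0, 25.0, "female_biased"),
            (10.0, 60.0, "strongly_female"),
            (10.0, 0.5, "male_specific"),
            (0.5, 10.0, "female_specific"),
        ],
    )
    def test_mf_categories(self, m, f, expected):
        assert classify_mf_bias(np.array([m]), np.array([f]))[0] == expected

    def test_proportion_comparison(self):
        cats = np.array(["strongly_male"] * 30 + ["unbiased"] * 70 +
                        ["strongly_male"] * 5 + ["unbiased"] * 95, dtype=object)
        is_x = np.array([False] * 100 + [True] * 100)
        px, pa, p = compare_bias_proportions(cats, is_x, {"strongly_male"})
        assert px == pytest.approx(0.05)
        assert pa == pytest.approx(0.30)
        assert p < 0.01
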