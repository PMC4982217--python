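import itertools

import numpy as np
import pytest
from scipy import stats

from beadprep import ComboSpec, CriterionScores
from beadprep.evaluate import (aggregate_reader_scores, auto_rate_plot,
                               bland_altman_pairs, cv_rank_score,
                               intra_rater_reliability, mean_sd_stats,
                               qq_mannwhitney, quantile_est, score_cv_percent,
                               score_skewness, score_tail, skewness_logS,
                               tail_length_T, total_score, volcano_stats)

from conftest import make_matrix


class TestQuantileEst:
    def test_median_of_1_to_100(self):
        assert quantile_est(np.arange(1, 101), 0.5) == 50.5

    def test_constant_vector(self):
        assert quantile_est([7.0, 7.0, 7.0], 0.9) == 7.0

    def test_interpolation_two_points(self):
        # linear interpolation: h = (n-1)q = 0.25 -> 0 + 0.25*10
        assert quantile_est([0.0, 10.0], 0.25) == 2.5

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            quantile_est([1.0], 0.5)


class TestSkewness:
    def test_symmetric_uniform_near_zero(self):
        x = np.random.default_rng(0).uniform(0, 1, 100000)
        assert abs(skewness_logS(x)) < 0.02

    def test_right_skew_positive(self):
        x = np.random.default_rng(0).exponential(1.0, 5000)
        assert skewness_logS(x) > 0

    def test_exponential_closed_form(self):
        # population quantiles of Exp(1): q_p = -log(1 - p)
        q = {p: -np.log(1 - p) for p in (0.025, 0.5, 0.975)}
        expected = np.log((q[0.975] - q[0.5]) / (q[0.5] - q[0.025]))
        x = np.random.default_rng(1).exponential(1.0, 400000)
        assert skewness_logS(x) == pytest.approx(expected, abs=0.05)

    def test_scale_invariant_under_positive_scaling(self, rng):
        x = rng.exponential(2.0, 2000)
        assert skewness_logS(3.7 * x) == pytest.approx(skewness_logS(x),
                                                       abs=1e-10)

    def test_degenerate_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            skewness_logS(np.array([1.0, 1.0, 1.0, 5.0]))


class TestTailLength:
    def test_normal_sample_near_1_704(self):
        x = np.random.default_rng(2).normal(0, 1, 1_000_000)
        assert tail_length_T(x) == pytest.approx(1.704, abs=0.01)

    def test_uniform_population_value(self):
        # exact uniform quantiles -> (0.975-0.025)/(0.875-0.125)
        expected = 0.95 / 0.75
        x = np.random.default_rng(3).uniform(0, 1, 500000)
        assert tail_length_T(x) == pytest.approx(expected, abs=0.01)

    def test_at_least_one(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, 50)
            assert tail_length_T(x) >= 1.0

    def test_location_scale_invariant(self, rng):
        x = rng.normal(5, 3, 1000)
        assert tail_length_T(-2.0 + 0.5 * x) == pytest.approx(
            tail_length_T(x), abs=1e-12)


class TestScoreBands:
    @pytest.mark.parametrize("log_s,expected", [
        (0.0, 2), (0.49, 2), (-0.49, 2),
        (0.5, 1), (-0.5, 1), (0.6, 1), (0.75, 1), (-0.75, 1),
        (0.76, 0), (-0.8, 0), (2.0, 0),
    ])
    def test_score_skewness(self, log_s, expected):
        assert score_skewness(log_s) == expected

    @pytest.mark.parametrize("t,expected", [
        (1.704, 2), (1.626, 2), (1.99, 2),
        (1.625, 1), (2.0, 1), (1.55, 1), (1.526, 1), (2.09, 1),
        (1.525, 0), (2.1, 0), (1.0, 0), (5.0, 0),
    ])
    def test_score_tail(self, t, expected):
        assert score_tail(t) == expected

    @pytest.mark.parametrize("pct,expected", [
        (10.0, 2), (50.0, 2), (50.1, 1), (80.0, 1), (80.1, 0), (100.0, 0),
    ])
    def test_score_cv_percent(self, pct, expected):
        assert score_cv_percent(pct) == expected


def _ref_matrix(ref_values):
    """Matrix whose two reference columns S0, S1 are given per analyte."""
    return make_matrix(np.asarray(ref_values, dtype=float))


class TestCvRankScore:
    def test_single_combo_cv_s_equals_n_analytes(self, rng):
        m = make_matrix(rng.uniform(10, 100, size=(7, 4)))
        out = cv_rank_score({"only": m}, ["S0", "S1", "S2", "S3"])
        assert out[0].cv_rank_sum == 7.0
        assert out[0].cv_percent == 100.0

    def test_uniformly_noisier_combo_gets_2A(self, rng):
        mean = rng.uniform(50, 100, 5)
        tight = np.column_stack([mean - 1.0, mean + 1.0])
        loose = np.column_stack([mean - 5.0, mean + 5.0])
        out = cv_rank_score({"tight": _ref_matrix(tight),
                             "loose": _ref_matrix(loose)}, ["S0", "S1"])
        by = {o.combo: o for o in out}
        assert by["tight"].cv_rank_sum == 5.0
        assert by["loose"].cv_rank_sum == 10.0

    def test_three_combo_hand_ranking_oracle(self, rng):
        # brute-force oracle: compute CVs directly and rank by sorting
        mats = {}
        raw = {}
        for name in ("c1", "c2", "c3"):
            vals = rng.uniform(20, 200, size=(4, 2))
            mats[name] = _ref_matrix(vals)
            raw[name] = vals
        expected = {name: 0.0 for name in mats}
        for i in range(4):
            cvs = {n: raw[n][i].std(ddof=1) / abs(raw[n][i].mean())
                   for n in mats}
            ordered = sorted(mats, key=lambda n: cvs[n])
            for rank, n in enumerate(ordered, start=1):
                expected[n] += rank
        out = {o.combo: o.cv_rank_sum for o in
               cv_rank_score(mats, ["S0", "S1"])}
        assert out == expected

    def test_near_zero_mean_analyte_dropped_symmetrically(self, rng):
        a = rng.uniform(10, 20, size=(3, 2))
        b = a.copy()
        b[0] = [1e-13, -1e-13]  # zero-mean analyte in one combo only
        out = cv_rank_score({"a": _ref_matrix(a), "b": _ref_matrix(b)},
                            ["S0", "S1"])
        # 2 analytes remain; bounds A <= CV_s <= A*M
        for o in out:
            assert 2.0 <= o.cv_rank_sum <= 4.0

    def test_bounds_and_total_rank_mass(self, rng):
        mats = {f"m{k}": make_matrix(rng.uniform(5, 50, size=(6, 3)))
                for k in range(4)}
        out = cv_rank_score(mats, ["S0", "S1", "S2"])
        A, M = 6, 4
        for o in out:
            assert A <= o.cv_rank_sum <= A * M
        assert sum(o.cv_rank_sum for o in out) == A * M * (M + 1) / 2


class TestMeanSd:
    def test_constant_matrix_flat(self):
        m = make_matrix(np.full((5, 4), 9.0))
        s = mean_sd_stats(m, ["S0", "S1", "S2", "S3"])
        np.testing.assert_array_equal(s.sd, 0.0)
        assert s.spearman == 0.0

    def test_homoscedastic_low_correlation(self, rng):
        base = rng.uniform(100, 1000, size=(200, 1))
        vals = base + rng.normal(0, 5.0, size=(200, 12))
        s = mean_sd_stats(make_matrix(vals), [f"S{j}" for j in range(12)])
        assert abs(s.spearman) < 0.15

    def test_multiplicative_noise_high_correlation(self, rng):
        base = np.exp(rng.normal(5, 1.5, size=(200, 1)))
        vals = base * np.exp(rng.normal(0, 0.2, size=(200, 12)))
        s = mean_sd_stats(make_matrix(vals), [f"S{j}" for j in range(12)])
        assert s.spearman > 0.5


class TestBlandAltman:
    def test_identical_replicates_all_zero(self):
        col = np.arange(1.0, 6.0)
        m = make_matrix(np.column_stack([col] * 4))
        s = bland_altman_pairs(m, ["S0", "S1", "S2", "S3"])
        np.testing.assert_array_equal(s.pair_diff, 0.0)
        assert s.mean_diff == 0.0

    def test_pair_count_for_12_replicates(self, rng):
        m = make_matrix(rng.uniform(1, 10, size=(3, 12)))
        s = bland_altman_pairs(m, [f"S{j}" for j in range(12)])
        assert s.pair_diff.size == 3 * 66  # 12 choose 2 per analyte

    def test_two_replicates_offset(self):
        a = np.array([1.0, 2.0, 3.0])
        c = 0.5
        m = make_matrix(np.column_stack([a, a + c]))
        s = bland_altman_pairs(m, ["S0", "S1"])
        np.testing.assert_allclose(s.pair_diff, -c)  # earlier minus later
        assert s.mean_diff == pytest.approx(-c)


def _exact_two_sided_p(a, b):
    """Enumeration oracle for the tie-free rank-sum test."""
    combined = np.concatenate([a, b])
    n, n_a = combined.size, len(a)
    ranks = stats.rankdata(combined)
    center = n_a * (n - n_a) / 2.0
    obs = abs(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0 - center)
    hits = total = 0
    for comb in itertools.combinations(range(n), n_a):
        u = ranks[list(comb)].sum() - n_a * (n_a + 1) / 2.0
        hits += abs(u - center) >= obs - 1e-9
        total += 1
    return hits / total


class TestVolcano:
    def test_identical_groups_relative_effect_half(self):
        m = make_matrix(np.full((2, 6), 4.0))
        out = volcano_stats(m, ["S0", "S1", "S2"], ["S3", "S4", "S5"])
        assert all(v.relative_effect == 0.5 for v in out)

    def test_complete_separation(self):
        m = make_matrix([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        out = volcano_stats(m, ["S0", "S1", "S2"], ["S3", "S4", "S5"])
        v = out[0]
        assert v.relative_effect == 1.0
        # exact enumeration gives 2/20 = 0.1 for the printed toy groups
        assert _exact_two_sided_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)
        assert v.p_value == pytest.approx(0.1, abs=0.02)

    def test_matches_enumeration_oracle_small_sizes(self, rng):
        for n_a in range(2, 6):
            for n_b in range(2, 6):
                x = rng.normal(0, 1, n_a)
                y = rng.normal(0.5, 1, n_b)
                m = make_matrix(np.concatenate([x, y])[None, :])
                out = volcano_stats(m, [f"S{j}" for j in range(n_a)],
                                    [f"S{j}" for j in range(n_a, n_a + n_b)])
                expected = _exact_two_sided_p(x, y)
                assert out[0].p_value == pytest.approx(expected, abs=0.02)

    def test_relative_effect_equals_u_over_nanb(self, rng):
        x = rng.normal(0, 1, 7)
        y = rng.normal(0.3, 1, 5)
        u_b = sum(1.0 for xi in x for yi in y if yi > xi)
        m = make_matrix(np.concatenate([x, y])[None, :])
        out = volcano_stats(m, [f"S{j}" for j in range(7)],
                            [f"S{j}" for j in range(7, 12)])
        assert out[0].relative_effect == pytest.approx(u_b / 35.0)

    def test_small_group_rejected(self):
        m = make_matrix(np.ones((1, 3)))
        with pytest.raises(ValueError, match=">= 2"):
            volcano_stats(m, ["S0"], ["S1", "S2"])


class TestQqMannWhitney:
    def test_same_seed_identical(self, rng):
        m = make_matrix(rng.normal(0, 1, size=(10, 8)))
        ids = [f"S{j}" for j in range(8)]
        z1, t1 = qq_mannwhitney(m, ids, n_reps=5, seed=3)
        z2, t2 = qq_mannwhitney(m, ids, n_reps=5, seed=3)
        np.testing.assert_array_equal(z1, z2)
        np.testing.assert_array_equal(t1, t2)

    def test_null_slope_near_one(self, rng):
        m = make_matrix(rng.normal(0, 1, size=(80, 18)))
        ids = [f"S{j}" for j in range(18)]
        z, theo = qq_mannwhitney(m, ids, n_reps=25, seed=1)
        slope = np.polyfit(theo, z, 1)[0]
        assert 0.9 <= slope <= 1.1

    def test_hand_computed_standardization(self):
        # n_reps=1, 2 analytes, 4 samples; reproduce the split and compute
        # U and its null standardization by hand
        vals = np.array([[10.0, 20.0, 30.0, 40.0],
                         [40.0, 30.0, 20.0, 10.0]])
        m = make_matrix(vals)
        ids = ["S0", "S1", "S2", "S3"]
        seed = 5
        z, _ = qq_mannwhitney(m, ids, n_reps=1, seed=seed)

        perm = np.random.default_rng(seed).permutation(4)
        g1, g2 = perm[:2], perm[2:]
        expected = []
        for row in vals:
            comb = np.concatenate([row[g1], row[g2]])
            ranks = stats.rankdata(comb)
            u1 = ranks[:2].sum() - 2 * 3 / 2.0
            sd = np.sqrt(2 * 2 / 12.0 * (4 + 1))  # tie-free
            expected.append((u1 - 2.0) / sd)
        np.testing.assert_allclose(z, np.sort(expected))

    def test_odd_group_trimmed(self, rng):
        m = make_matrix(rng.normal(size=(5, 5)))
        z, _ = qq_mannwhitney(m, [f"S{j}" for j in range(5)], n_reps=2, seed=0)
        assert z.size == 5 * 2

    def test_seed_required(self, rng):
        m = make_matrix(rng.normal(size=(5, 4)))
        with pytest.raises(ValueError, match="seed"):
            qq_mannwhitney(m, [f"S{j}" for j in range(4)])


class TestReaderAggregation:
    def test_all_good(self):
        assert aggregate_reader_scores([2] * 15) == (30, 2)

    def test_all_fair(self):
        assert aggregate_reader_scores([1] * 15) == (15, 1)

    def test_sum_10_is_poor(self):
        ratings = [1] * 10 + [0] * 5
        assert aggregate_reader_scores(ratings) == (10, 0)

    @pytest.mark.parametrize("total,expected", [
        (0, 0), (10, 0), (11, 1), (20, 1), (21, 2), (30, 2)])
    def test_band_edges(self, total, expected):
        ratings = [2] * (total // 2) + [1] * (total % 2)
        ratings += [0] * (15 - len(ratings))
        s, cls = aggregate_reader_scores(ratings)
        assert s == total and cls == expected

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError, match="15"):
            aggregate_reader_scores([2] * 14)

    def test_invalid_value_rejected(self):
        with pytest.raises(ValueError):
            aggregate_reader_scores([2] * 14 + [5])


class TestIntraRater:
    def test_identical_rounds(self):
        assert intra_rater_reliability([3, 7, 11], [3, 7, 11]) == pytest.approx(1.0)

    def test_reversed_ordering(self):
        assert intra_rater_reliability([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_built_table_matches_closed_form(self):
        r1 = np.array([12.0, 8.0, 5.0])
        r2 = np.array([11.0, 9.0, 4.0])
        n = 3
        num = n * (r1 * r2).sum() - r1.sum() * r2.sum()
        den = np.sqrt(n * (r1 ** 2).sum() - r1.sum() ** 2) * \
            np.sqrt(n * (r2 ** 2).sum() - r2.sum() ** 2)
        assert intra_rater_reliability(r1, r2) == pytest.approx(num / den)


class TestAutoRate:
    def test_homoscedastic_mean_sd_good(self, rng):
        base = rng.uniform(100, 1000, size=(200, 1))
        vals = base + rng.normal(0, 5.0, size=(200, 12))
        s = mean_sd_stats(make_matrix(vals), [f"S{j}" for j in range(12)])
        assert auto_rate_plot("mean_sd", s) == 2

    def test_multiplicative_raw_mean_sd_poor(self, rng):
        base = np.exp(rng.normal(5, 1.5, size=(200, 1)))
        vals = base * np.exp(rng.normal(0, 0.2, size=(200, 12)))
        s = mean_sd_stats(make_matrix(vals), [f"S{j}" for j in range(12)])
        assert auto_rate_plot("mean_sd", s) == 0

    def test_symmetric_effects_volcano_good(self, rng):
        n_a, n_b = 12, 12
        vals = rng.normal(0, 1, size=(60, n_a + n_b))
        vals[:10, n_a:] += 3.0   # up in cases
        vals[10:20, n_a:] -= 3.0  # down in cases
        m = make_matrix(vals)
        vo = volcano_stats(m, [f"S{j}" for j in range(n_a)],
                           [f"S{j}" for j in range(n_a, n_a + n_b)])
        assert auto_rate_plot("volcano", vo) == 2

    def test_clean_bland_altman_good(self, rng):
        base = rng.uniform(10, 20, size=(100, 1))
        vals = base + rng.normal(0, 0.5, size=(100, 6))
        s = bland_altman_pairs(make_matrix(vals), [f"S{j}" for j in range(6)])
        assert auto_rate_plot("bland_altman", s) == 2

    def test_funnel_bland_altman_poor(self, rng):
        base = np.exp(rng.normal(3, 1, size=(200, 1)))
        vals = base * np.exp(rng.normal(0, 0.3, size=(200, 6)))
        s = bland_altman_pairs(make_matrix(vals), [f"S{j}" for j in range(6)])
        assert auto_rate_plot("bland_altman", s) == 0

    def test_unknown_criterion(self):
        with pytest.raises(ValueError):
            auto_rate_plot("sparkline", None)


class TestTotalScore:
    def test_all_good_is_12(self):
        s = CriterionScores(ComboSpec("log2", "quantile"), 2, 2, 2, 2, 2, 2)
        assert total_score(s) == 12

    def test_all_poor_is_0(self):
        s = CriterionScores(ComboSpec("log2", "quantile"), 0, 0, 0, 0, 0, 0)
        assert total_score(s) == 0

    def test_mixed(self):
        s = CriterionScores(ComboSpec("log2", "quantile"), 2, 1, 0, 2, 1, 0)
        assert total_score(s) == 6
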