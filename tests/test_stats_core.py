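"""Unit and property tests for AICc ranking and the classical tests."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from oacrab.stats_core import (
    GroupedSample,
    ModelScore,
    aicc,
    fisher_lsd,
    kruskal_wallis,
    levene,
    one_way_anova,
    rank_models,
)


class TestAicc:
    @pytest.mark.parametrize(
        "loglik,k,n,expected",
        [
            (0.0, 1, 100, 2.0 + 4.0 / 98.0),
            (-1000.0, 3, 90, 2000.0 + 6.0 + 24.0 / 86.0),
        ],
    )
    def test_formula(self, loglik, k, n, expected):
        assert aicc(ModelScore("m", k, loglik, n)) == pytest.approx(expected, abs=1e-10)

    def test_small_sample_guard(self):
        with pytest.raises(ValueError):
            ModelScore("m", 3, 0.0, 4)  # n <= K + 1

    def test_converges_to_aic_for_large_n(self):
        s = ModelScore("m", 3, -50.0, 10**9)
        assert abs(aicc(s) - (100.0 + 6.0)) < 1e-6

    def test_on_fitted_survival_loglik(self):
        """AICc of a fitted hazard model equals the hand-evaluated formula."""
        from oacrab.survival import STRUCTURES, SurvivalRecord, fit_mortality

        recs = [
            SurvivalRecord(f"c{i}", "control", 0, d, s)
            for i, (d, s) in enumerate(
                [(5, "died"), (12, "died"), (30, "censored"), (30, "censored"),
                 (17, "died"), (30, "censored"), (8, "died"), (30, "censored"),
                 (22, "died"), (30, "censored")]
            )
        ]
        fit = fit_mortality(recs, STRUCTURES["all_same"])
        score = ModelScore("all_same", 1, fit.loglik, 10)
        assert aicc(score) == pytest.approx(-2 * fit.loglik + 2 + 4 / 8, abs=1e-12)


class TestRankModels:
    def test_published_style_ranking(self):
        """Re-ranking three printed AICc values reproduces the delta/weight columns."""
        scores = [
            ModelScore("All Different", 3, -1100.0, 90),
            ModelScore("Control<Acidified", 2, -1340.0, 90),
            ModelScore("All Same", 1, -1840.0, 90),
        ]
        ranking = rank_models(scores, precomputed_aicc=[2232.82, 2703.17, 3687.07])
        t = ranking.table
        assert list(t["model"]) == ["All Different", "Control<Acidified", "All Same"]
        assert t["delta_aicc"].tolist() == pytest.approx([0.0, 470.35, 1454.25])
        assert t["weight"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert t["weight"].iloc[1] < 1e-50
        assert ranking.co_best == ["All Different"]

    def test_two_equal_models_split_weight(self):
        scores = [ModelScore("a", 1, -10.0, 50), ModelScore("b", 1, -10.0, 50)]
        t = rank_models(scores).table
        assert t["weight"].tolist() == pytest.approx([0.5, 0.5])
        assert t["delta_aicc"].tolist() == pytest.approx([0.0, 0.0])

    def test_delta_two_relative_likelihood(self):
        scores = [ModelScore("a", 1, 0.0, 50), ModelScore("b", 1, -1.0, 50)]
        t = rank_models(scores).table
        assert t["rel_likelihood"].iloc[1] == pytest.approx(np.exp(-1.0), abs=1e-12)
        # both within the delta < 2 tie band
        assert rank_models(scores).co_best == ["a", "b"]

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            rank_models([])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=-500, max_value=0), min_size=2, max_size=6)
    )
    def test_weights_sum_to_one_and_best_has_max_weight(self, logliks):
        scores = [ModelScore(f"m{i}", 2, ll, 100) for i, ll in enumerate(logliks)]
        t = rank_models(scores).table
        assert t["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert t["delta_aicc"].min() == 0.0
        assert t["weight"].iloc[0] == t["weight"].max()
        # weight order matches -delta order
        assert (t["weight"].diff().dropna() <= 1e-15).all()


class TestAnova:
    def test_identical_group_means_give_zero_f(self):
        v = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        g = np.array(["a"] * 3 + ["b"] * 3)
        assert one_way_anova((v, g))["F"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_sums_of_squares(self):
        # groups {1,2,3}, {2,3,4}, {6,7,8}: means 2,3,7, grand mean 4
        # SSB = 3[(2-4)^2+(3-4)^2+(7-4)^2] = 42 on 2 df; SSW = 6 on 6 df
        # F = (42/2)/(6/6) = 21
        v = np.array([1.0, 2, 3, 2, 3, 4, 6, 7, 8])
        g = np.repeat(["a", "b", "c"], 3)
        res = one_way_anova((v, g))
        assert res["F"] == pytest.approx(21.0, abs=1e-10)
        assert res["df"] == (2, 6)
        assert res["p"] == pytest.approx(float(sps.f.sf(21.0, 2, 6)), abs=1e-12)

    def test_p_matches_permutation_null(self, rng):
        """F-distribution p agrees with a 10,000-shuffle permutation null."""
        v = rng.normal(0, 1, 12)
        v[8:] += 1.2
        g = np.repeat(["a", "b", "c"], 4)
        p_f = one_way_anova((v, g))["p"]
        f_obs = one_way_anova((v, g))["F"]
        hits = 0
        B = 10_000
        for _ in range(B):
            gp = rng.permutation(g)
            hits += one_way_anova((v, gp))["F"] >= f_obs - 1e-12
        assert abs(p_f - hits / B) < 0.01

    def test_invariant_to_shift_and_scale(self, rng):
        v = rng.normal(0, 1, 15)
        g = np.repeat(["a", "b", "c"], 5)
        f0 = one_way_anova((v, g))["F"]
        assert one_way_anova((v + 7.3, g))["F"] == pytest.approx(f0, rel=1e-9)
        assert one_way_anova((v * 4.1, g))["F"] == pytest.approx(f0, rel=1e-9)

    def test_degenerate_signalled(self):
        v = np.ones(6)
        g = np.repeat(["a", "b"], 3)
        with pytest.raises(ZeroDivisionError):
            one_way_anova((v, g))

    def test_grouped_sample_validation(self):
        with pytest.raises(ValueError):
            GroupedSample(np.array([1.0, 2.0]), np.array(["a", "a"]))


class TestLevene:
    def test_definitional_identity_with_anova_on_deviations(self, rng):
        v = rng.normal(0, 1, 18)
        v[6:12] *= 3.0
        g = np.repeat(["a", "b", "c"], 6)
        w = levene((v, g))["W"]
        dev = np.concatenate(
            [np.abs(v[g == lab] - v[g == lab].mean()) for lab in ["a", "b", "c"]]
        )
        f = one_way_anova((dev, g))["F"]
        assert w == pytest.approx(f, rel=1e-10)

    def test_detects_scaled_group(self, rng):
        v = rng.normal(0, 1, 60)
        v[40:] *= 10.0
        g = np.repeat(["a", "b", "c"], 20)
        res = levene((v, g))
        assert res["p"] < 0.05

    def test_identical_deviation_distributions(self):
        v = np.array([1.0, 2, 3, 11, 12, 13])
        g = np.repeat(["a", "b"], 3)
        assert levene((v, g))["W"] == pytest.approx(0.0, abs=1e-12)


class TestKruskalWallis:
    def test_equal_rank_sums_give_zero_h(self):
        # 1..9 split so each group's rank sum is 15
        v = np.array([1.0, 6, 8, 2, 4, 9, 3, 5, 7])
        g = np.repeat(["a", "b", "c"], 3)
        assert kruskal_wallis((v, g))["H"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_ranked_computation(self):
        # 3 groups of 5 distinct values; H computed by hand from rank sums:
        # H = 12/(N(N+1)) * sum R_j^2/n_j - 3(N+1)
        v = np.array([3.0, 1, 4, 9, 7, 2, 5, 6, 11, 8, 10, 12, 13, 15, 14])
        g = np.repeat(["a", "b", "c"], 5)
        ranks = {val: i + 1 for i, val in enumerate(sorted(v))}
        r = np.array([ranks[x] for x in v])
        rank_sums = [r[g == lab].sum() for lab in ["a", "b", "c"]]
        h_hand = 12.0 / (15 * 16) * sum(s**2 / 5 for s in rank_sums) - 3 * 16
        assert kruskal_wallis((v, g))["H"] == pytest.approx(h_hand, abs=1e-10)

    def test_exact_p_matches_exhaustive_enumeration(self):
        """Small-sample exact p equals an independent enumeration of all
        1680 distinct assignments of 9 values to three groups of 3."""
        v = np.array([1.0, 2, 4, 3, 5, 7, 6, 8, 9])
        g = np.repeat(["a", "b", "c"], 3)
        res = kruskal_wallis((v, g), exact=True)
        ranks = {val: i + 1 for i, val in enumerate(sorted(v))}
        r = np.array([ranks[x] for x in v])

        def h_of(parts):
            return 12.0 / (9 * 10) * sum(
                len(p) * (r[list(p)].mean() - 5.0) ** 2 for p in parts
            )

        obs = h_of([np.where(g == lab)[0] for lab in ["a", "b", "c"]])
        hs = []
        idx = set(range(9))
        for a in combinations(range(9), 3):
            rest = idx - set(a)
            for b in combinations(sorted(rest), 3):
                hs.append(h_of([list(a), list(b), sorted(rest - set(b))]))
        p_exact = np.mean(np.asarray(hs) >= obs - 1e-12)
        assert abs(res["p"] - p_exact) < 0.01

    def test_all_tied(self):
        v = np.ones(9)
        g = np.repeat(["a", "b", "c"], 3)
        assert kruskal_wallis((v, g))["H"] == 0.0

    def test_invariant_to_monotone_transform(self, rng):
        v = rng.normal(0, 1, 15)
        g = np.repeat(["a", "b", "c"], 5)
        h0 = kruskal_wallis((v, g))["H"]
        assert kruskal_wallis((np.exp(v), g))["H"] == pytest.approx(h0, rel=1e-12)
        assert kruskal_wallis((v**3, g))["H"] == pytest.approx(h0, rel=1e-12)


class TestFisherLsd:
    def test_pairwise_t_equals_hand_formula(self):
        v = np.array([1.0, 2, 3, 2, 3, 4, 6, 7, 8])
        g = np.repeat(["a", "b", "c"], 3)
        table = fisher_lsd((v, g))
        msw = 6.0 / 6.0  # SSW=6 on 6 df (hand computed)
        for _, row in table.iterrows():
            t_hand = (row["mean_a"] - row["mean_b"]) / np.sqrt(msw * (2.0 / 3.0))
            assert row["t"] == pytest.approx(t_hand, abs=1e-10)
            assert row["df"] == 6

    def test_identical_groups_give_t_zero(self):
        v = np.array([1.0, 2, 3, 1, 2, 3])
        g = np.repeat(["a", "b"], 3)
        row = fisher_lsd((v, g)).iloc[0]
        assert row["t"] == pytest.approx(0.0, abs=1e-12)
        assert row["p"] == pytest.approx(1.0, abs=1e-12)

    def test_two_groups_equals_pooled_t_test(self, rng):
        va, vb = rng.normal(0, 1, 8), rng.normal(0.8, 1, 6)
        v = np.concatenate([va, vb])
        g = np.array(["a"] * 8 + ["b"] * 6)
        row = fisher_lsd((v, g)).iloc[0]
        t_ref, p_ref = sps.ttest_ind(va, vb, equal_var=True)
        assert row["t"] == pytest.approx(float(t_ref), rel=1e-10)
        assert row["p"] == pytest.approx(float(p_ref), rel=1e-10)

    def test_omnibus_gate(self):
        v = np.array([1.0, 2, 3, 1.1, 2.1, 3.1, 0.9, 2.0, 3.0])
        g = np.repeat(["a", "b", "c"], 3)
        omnibus = one_way_anova((v, g))
        assert omnibus["p"] > 0.05
        with pytest.raises(ValueError):
            fisher_lsd((v, g), omnibus)
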