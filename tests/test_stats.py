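"""Statistics: exact Wilcoxon, Cohen's kappa, bootstrap power, summaries."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, wilcoxon as scipy_wilcoxon
from sklearn.metrics import cohen_kappa_score

from graftscore import phantom, stats


def enumerate_wilcoxon_p(d):
    """Oracle: brute-force enumeration of all 2^m sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    m = len(d)
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [
            sum(r for r, s in zip(ranks, signs) if s > 0)
            for signs in product([1, -1], repeat=m)
        ]
    )
    return min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        r = stats.wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
        assert r.p_value == 1.0 and r.n_effective == 0
        assert "convention" in r.method_detail

    def test_three_positive_differences(self):
        r = stats.wilcoxon_signed_rank([2, 3, 4], [1, 1, 1], mode="exact")
        assert r.p_value == pytest.approx(0.25)

    def test_five_positive_differences(self):
        r = stats.wilcoxon_signed_rank([2, 4, 6, 8, 10], [1, 1, 1, 1, 1], mode="exact")
        assert r.p_value == pytest.approx(0.0625)

    @pytest.mark.parametrize("seed", range(12))
    def test_exact_equals_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 13))
        d = rng.integers(-6, 7, size=m)
        if (d == 0).all():
            d[0] = 1
        ours = stats.wilcoxon_signed_rank(d, np.zeros(m), mode="exact")
        assert ours.p_value == pytest.approx(enumerate_wilcoxon_p(d), abs=1e-14)

    @pytest.mark.parametrize("zero_method", ["discard", "pratt"])
    def test_zero_methods_run_and_report(self, zero_method):
        r = stats.wilcoxon_signed_rank(
            [1, 1, 3, 5], [1, 1, 1, 1], zero_method=zero_method, mode="exact"
        )
        assert 0 < r.p_value <= 1
        assert zero_method in r.method_detail

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            d = (rng.permutation(30)[:10] + 1.5) * rng.choice([-1, 1], 10)
            ours = stats.wilcoxon_signed_rank(d, np.zeros(10), mode="exact").p_value
            theirs = scipy_wilcoxon(d, mode="exact").pvalue
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_normal_approximation_close_to_exact_for_moderate_m(self):
        """Tie-corrected normal approximation tracks the exact p within 10%.

        Relative accuracy is asserted outside the extreme tail (exact
        p >= 0.05): a Gaussian tail cannot track a discrete distribution's
        relative error at p ~ 1e-3, and the approximation is only ever used
        as a large-m stand-in where such precision is not claimed.
        """
        rng = np.random.default_rng(9)
        checked = 0
        for _ in range(40):
            m = int(rng.integers(26, 41))
            d = rng.integers(-3, 4, size=m).astype(float)
            d[d == 0] = 1.0
            exact = stats.wilcoxon_signed_rank(d, np.zeros(m), mode="exact").p_value
            if exact < 0.05:
                continue
            approx = stats.wilcoxon_signed_rank(
                d, np.zeros(m), mode="auto", exact_threshold=25
            ).p_value
            assert approx == pytest.approx(exact, rel=0.10)
            checked += 1
        assert checked >= 10


class TestKappa:
    def test_perfect_agreement(self):
        assert stats.cohen_kappa([0, 1, 2, 3] * 4, [0, 1, 2, 3] * 4) == 1.0

    def test_hand_computed_two_by_two_table(self):
        # counts: both-0 40, a0/b1 10, a1/b0 10, both-1 40 -> po=.8, pe=.5
        a = [0] * 50 + [1] * 50
        b = [0] * 40 + [1] * 10 + [0] * 10 + [1] * 40
        assert stats.cohen_kappa(a, b, categories=(0, 1)) == pytest.approx(
            0.6, abs=1e-12
        )

    def test_chance_level_agreement_near_zero(self):
        rng = np.random.default_rng(12)
        a = rng.integers(0, 4, 10_000)
        b = rng.integers(0, 4, 10_000)
        assert abs(stats.cohen_kappa(a, b)) < 0.05

    def test_degenerate_single_category_agreement(self):
        assert stats.cohen_kappa([2] * 10, [2] * 10) == 1.0

    def test_matches_sklearn(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 4, 200)
        b = np.where(rng.random(200) < 0.7, a, rng.integers(0, 4, 200))
        assert stats.cohen_kappa(a, b) == pytest.approx(
            cohen_kappa_score(a, b), abs=1e-12
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            stats.cohen_kappa([1, 2], [1, 2, 3])


class TestBootstrapPower:
    def test_null_power_close_to_alpha(self):
        pool = np.concatenate([np.arange(13), np.arange(13)])[:21]
        res = stats.bootstrap_power(pool, pool, alpha=0.05, n_reps=2000, seed=3)
        se3 = 3 * np.sqrt(0.05 * 0.95 / 2000)
        assert res.power == pytest.approx(0.05, abs=se3)

    def test_separated_distributions_reach_full_power(self):
        cleft = np.array([0, 1, 2, 3, 4] * 5)[:21]
        control = np.array([10, 11, 12] * 7)
        res = stats.bootstrap_power(cleft, control, alpha=0.05, n_reps=500, seed=1)
        assert res.power >= 0.99

    def test_power_monotone_in_alpha(self):
        rng = np.random.default_rng(0)
        cleft = rng.integers(0, 8, 21)
        control = rng.integers(5, 13, 21)
        p_small = stats.bootstrap_power(cleft, control, alpha=0.01, n_reps=400, seed=2)
        p_large = stats.bootstrap_power(cleft, control, alpha=0.05, n_reps=400, seed=2)
        assert p_large.power >= p_small.power

    def test_deterministic_under_seed(self):
        cleft = np.arange(21) % 5
        control = np.arange(21) % 4 + 8
        a = stats.bootstrap_power(cleft, control, n_reps=200, seed=9)
        b = stats.bootstrap_power(cleft, control, n_reps=200, seed=9)
        assert a.power == b.power and a.p_critical == b.p_critical

    def test_degenerate_one_point_distributions(self):
        res = stats.bootstrap_power([5] * 21, [5] * 21, alpha=0.05, n_reps=100, seed=0)
        assert res.power == 0.05
        assert "degenerate" in res.method_detail


class TestSummaries:
    def test_site_summary_conserves_mass(self):
        dists = [[0.25, 0.25, 0.25, 0.25]] * 4
        df = phantom.generate_cohort_scores(21, dists, dists, seed=1)
        out = stats.summarize_sites(df, "cleft")
        assert out["per_level"].to_numpy().sum() == 84
        assert (out["per_level"].sum(axis=1) == 21).all()
        assert out["pooled"].sum() == 84

    def test_missing_level_raises_completeness_error(self):
        dists = [[0.25, 0.25, 0.25, 0.25]] * 4
        df = phantom.generate_cohort_scores(5, dists, dists, seed=1)
        with pytest.raises(ValueError, match="missing levels \\[9\\]"):
            stats.summarize_sites(df[df["level_mm"] != 9], "cleft")

    def test_single_patient_total(self):
        out = stats.summarize_totals({"cleft": [7]})
        assert out["cleft"]["category_pct"]["moderate"] == 100.0
        assert out["cleft"]["median"] == 7

    def test_percentages_sum_to_hundred_with_rounding(self):
        rng = np.random.default_rng(2)
        totals = rng.integers(0, 13, 21)
        out = stats.summarize_totals({"cleft": totals})
        assert sum(out["cleft"]["category_pct"].values()) == pytest.approx(
            100.0, abs=0.02
        )

    def test_expand_counts_roundtrip(self):
        counts = [2, 0, 1] + [0] * 10
        totals = stats.expand_counts(counts)
        assert list(totals) == [0, 0, 2]
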