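import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tdufe import (
    bh_adjust,
    chi2_pvalues,
    flatness_objective,
    optimize_sigma,
    select_genes,
)


def brute_force_bh(p):
    """O(m^2) literal step-up definition: adj_i = min over q>=rank(i) of p_(q)*m/q."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    sorted_p = p[order]
    for rank in range(m):
        candidates = [sorted_p[q] * m / (q + 1) for q in range(rank, m)]
        adj[order[rank]] = min(1.0, min(candidates))
    return adj


class TestChi2Pvalues:
    def test_zero_statistic_gives_p_one(self):
        assert chi2_pvalues(np.array([0.0]), 1.0)[0] == pytest.approx(1.0)

    def test_one_sigma_matches_gaussian_two_sided(self):
        # chi2_1 upper tail at 1 == 2*(1 - Phi(1)) = 0.31731...
        p = chi2_pvalues(np.array([1.0]), 1.0)[0]
        assert p == pytest.approx(0.3173105, abs=1e-6)
        assert p == pytest.approx(2 * (1 - stats.norm.cdf(1.0)), abs=1e-12)

    def test_five_percent_quantile(self):
        p = chi2_pvalues(np.array([1.959964]), 1.0)[0]
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_matches_scipy_chi2_sf(self):
        u = np.random.default_rng(0).normal(size=1000)
        np.testing.assert_allclose(
            chi2_pvalues(u, 0.7), stats.chi2.sf((u / 0.7) ** 2, df=1), atol=1e-13
        )

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1), st.floats(0.01, 100.0))
    def test_scale_invariance(self, seed, c):
        u = np.random.default_rng(seed).normal(size=50)
        np.testing.assert_allclose(
            chi2_pvalues(c * u, c * 1.3), chi2_pvalues(u, 1.3), atol=1e-12
        )

    def test_monotone_in_abs_u(self):
        u = np.linspace(0, 5, 100)
        p = chi2_pvalues(u, 1.0)
        assert (np.diff(p) <= 0).all()

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            chi2_pvalues(np.array([1.0]), 0.0)


class TestBHAdjust:
    def test_all_equal_unchanged(self):
        p = np.full(5, 0.2)
        np.testing.assert_allclose(bh_adjust(p), p)

    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.5])),
            [0.04, 0.04, 0.04, 0.5],
            atol=1e-12,
        )

    def test_matches_brute_force_on_200_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_adjusted_at_least_raw(self):
        p = np.random.default_rng(1).uniform(size=100)
        assert (bh_adjust(p) >= p - 1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))


class TestFlatnessObjective:
    def test_uniform_over_bin_centers_is_zero(self):
        n_bins = 20
        p = (np.arange(n_bins) + 0.5) / n_bins
        assert flatness_objective(p, n_bins=n_bins, exclude_low_p_bins=0) == 0.0

    def test_one_hot_closed_form(self):
        # all p identical -> counts (N, 0, ..., 0); sd = N*sqrt(B-1)/B
        n, b = 50, 25
        p = np.full(n, 0.999)  # 1-p lands in the first bin
        expected = n * np.sqrt(b - 1) / b
        assert flatness_objective(p, n_bins=b, exclude_low_p_bins=0) == pytest.approx(expected)

    def test_true_sigma_flatter_than_wrong_sigma(self):
        hits = 0
        for seed in range(100):
            u = np.random.default_rng(seed).normal(0, 1, 5000)
            obj = {s: flatness_objective(chi2_pvalues(u, s)) for s in (0.5, 1.0, 2.0)}
            hits += obj[1.0] < obj[0.5] and obj[1.0] < obj[2.0]
        assert hits >= 95

    def test_validation(self):
        with pytest.raises(ValueError, match="n_bins"):
            flatness_objective(np.array([0.5]), n_bins=5)
        with pytest.raises(ValueError, match="empty"):
            flatness_objective(np.array([]))


class TestOptimizeSigma:
    def test_recovers_unit_sigma_within_10_percent(self):
        u = np.random.default_rng(0).normal(0, 1, 10_000)
        sigma, profile = optimize_sigma(u)
        assert abs(sigma - 1.0) < 0.1
        assert len(profile) == 101
        assert profile["objective"].min() >= 0

    def test_outlier_contaminated_within_15_percent(self):
        rng = np.random.default_rng(1)
        u = np.concatenate([rng.normal(0, 1, 9500), rng.normal(0, 5, 500)])
        sigma, _ = optimize_sigma(u)
        assert abs(sigma - 1.0) < 0.15

    def test_degenerate_all_zero_raises(self):
        with pytest.raises(ValueError, match="constant"):
            optimize_sigma(np.zeros(1000))

    def test_too_few_entries_raises(self):
        with pytest.raises(ValueError, match="at least"):
            optimize_sigma(np.random.default_rng(2).normal(size=50))


class TestSelectGenes:
    def test_null_uniformity_ks_with_true_sigma(self):
        # raw p-values exactly uniform under the null: KS below the 1% critical
        # value 1.628/sqrt(N) in at least 95/100 seeds
        crit = 1.628 / np.sqrt(10_000)
        hits = 0
        for seed in range(100):
            u = np.random.default_rng(seed).normal(0, 1, 10_000)
            p = chi2_pvalues(u, 1.0)
            hits += stats.kstest(p, "uniform").statistic < crit
        assert hits >= 95

    def test_pure_null_selects_almost_nothing(self):
        fractions = []
        for seed in range(20):
            u = np.random.default_rng(seed).normal(0, 1, 10_000)
            res = select_genes(u, threshold=0.01)
            fractions.append(res.selected.mean())
        assert max(fractions) <= 0.02

    def test_planted_outliers_recovered(self):
        rng = np.random.default_rng(3)
        n, n_sig = 10_000, 500
        u = rng.normal(0, 1, n)
        sig = rng.choice(n, n_sig, replace=False)
        u[sig] = rng.choice([-6.0, 6.0], n_sig) + rng.normal(0, 1, n_sig)
        res = select_genes(u, threshold=0.01)
        truth = np.zeros(n, bool)
        truth[sig] = True
        tp = (res.selected & truth).sum()
        precision = tp / res.selected.sum()
        recall = tp / n_sig
        assert precision >= 0.9 and recall >= 0.9

    def test_selection_monotone_in_threshold(self):
        u = np.random.default_rng(4).normal(0, 1, 2000)
        u[:20] += 8
        loose = select_genes(u, threshold=0.05)
        tight = select_genes(u, threshold=0.001)
        assert not (tight.selected & ~loose.selected).any()

    def test_selected_iff_below_threshold(self):
        u = np.random.default_rng(5).normal(0, 1, 2000)
        res = select_genes(u, threshold=0.01)
        np.testing.assert_array_equal(res.selected, res.p_adjusted < 0.01)
        assert ((res.p_raw >= 0) & (res.p_raw <= 1)).all()
        assert (res.p_adjusted >= res.p_raw - 1e-15).all()
        assert res.sigma > 0

    def test_fixed_sigma_bypasses_optimizer(self):
        u = np.random.default_rng(6).normal(0, 2, 1000)
        res = select_genes(u, sigma=2.0)
        assert res.sigma == 2.0
        np.testing.assert_allclose(res.p_raw, chi2_pvalues(u, 2.0))

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            select_genes(np.random.default_rng(7).normal(size=500), threshold=1.5)

    def test_to_frame_columns(self):
        u = np.random.default_rng(8).normal(size=200)
        res = select_genes(u, sigma=1.0)
        df = res.to_frame([f"g{i}" for i in range(200)], u)
        assert list(df.columns) == ["feature_id", "u_value", "p_raw", "p_adjusted", "selected"]
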