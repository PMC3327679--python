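import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate as spi
from scipy import stats

from triomics.io_tables import ExpressionMatrix, SampleMeta
from triomics.preprocess import (
    NormexpParams,
    collapse_replicates,
    estimate_normexp_params,
    filter_low_signal,
    lowess_normalize,
    normexp_correct,
    rank_invariant_normalize,
    vsn_like_normalize,
)
from tests.conftest import make_matrix


class TestNormexp:
    def test_degenerate_limit_is_foreground_plus_offset(self):
        fg = np.array([10.0, 50.0, 200.0])
        bg = np.zeros(3)
        params = NormexpParams(mu=0.0, sigma=1e-9, alpha=1e9, offset=16.0)
        out = normexp_correct(fg, bg, params)
        assert np.allclose(out, fg + 16.0, atol=1e-3)

    def test_conditional_expectation_matches_quadrature(self):
        mu, sigma, alpha, x = 100.0, 20.0, 500.0, 150.0

        def joint(s):
            return stats.expon.pdf(s, scale=alpha) * stats.norm.pdf(x - s, mu, sigma)

        hi = x + 10 * sigma
        num, _ = spi.quad(lambda s: s * joint(s), 0, hi)
        den, _ = spi.quad(joint, 0, hi)
        expected = num / den
        params = NormexpParams(mu=mu, sigma=sigma, alpha=alpha, offset=0.0)
        got = normexp_correct(np.array([x]), np.zeros(1), params)[0]
        assert got == pytest.approx(expected, rel=1e-6)

    @given(
        x=st.floats(min_value=-500.0, max_value=5000.0),
        mu=st.floats(min_value=0.0, max_value=500.0),
        sigma=st.floats(min_value=0.1, max_value=100.0),
        alpha=st.floats(min_value=1.0, max_value=5000.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_output_strictly_positive(self, x, mu, sigma, alpha):
        params = NormexpParams(mu=mu, sigma=sigma, alpha=alpha, offset=0.0)
        out = normexp_correct(np.array([max(x, 0.0)]), np.zeros(1), params)
        assert np.all(out > 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            NormexpParams(mu=0, sigma=-1, alpha=1)
        with pytest.raises(ValueError):
            NormexpParams(mu=0, sigma=1, alpha=0)

    def test_moment_estimation_recovers_scales(self):
        rng = np.random.default_rng(2)
        n = 20000
        bg_true = rng.normal(100, 20, n)
        signal = rng.exponential(800, n)
        fg = bg_true + signal
        params = estimate_normexp_params(fg, bg_true)
        assert params.mu == pytest.approx(100, rel=0.05)
        assert params.sigma == pytest.approx(20, rel=0.1)
        assert params.alpha == pytest.approx(800, rel=0.1)


class TestLowess:
    def test_zero_ratios_stay_zero(self):
        A = np.linspace(5, 15, 50)
        out = lowess_normalize(np.zeros(50), A)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_constant_shift_removed(self):
        A = np.linspace(5, 15, 50)
        out = lowess_normalize(np.full(50, 0.5), A)
        assert np.max(np.abs(out)) < 1e-6

    def test_linear_trend_removed_per_decile(self):
        rng = np.random.default_rng(3)
        A = rng.uniform(6, 14, 2000)
        M = 0.3 * A + rng.normal(0, 0.01, 2000)
        out = lowess_normalize(M, A)
        deciles = np.quantile(A, np.linspace(0, 1, 11))
        for lo, hi in zip(deciles[:-1], deciles[1:]):
            sel = (A >= lo) & (A <= hi)
            assert abs(np.median(out[sel])) < 0.02

    def test_missing_pairs_pass_through(self):
        A = np.linspace(5, 15, 30)
        M = np.full(30, 0.7)
        M[4] = np.nan
        out = lowess_normalize(M, A)
        assert np.isnan(out[4])
        assert np.max(np.abs(out[~np.isnan(out)])) < 1e-6

    def test_too_few_finite_pairs_error(self):
        with pytest.raises(ValueError, match="finite"):
            lowess_normalize(np.ones(5), np.arange(5.0))

    def test_shift_equivariance(self):
        rng = np.random.default_rng(4)
        A = rng.uniform(5, 15, 300)
        M = rng.normal(0, 0.3, 300)
        assert np.allclose(
            lowess_normalize(M + 2.5, A), lowess_normalize(M, A), atol=1e-6
        )


class TestVsnLike:
    def test_large_intensities_behave_like_log2(self):
        x = np.geomspace(1e4, 1e7, 200)
        m = make_matrix(np.column_stack([x, x]), layer="miRNA",
                        conditions=["sensitive", "resistant"])
        out = vsn_like_normalize(m, cofactor=100.0).values[:, 0]
        rel_err = np.abs(out - np.log2(x)) / np.log2(x)
        assert np.max(rel_err) < 0.01

    def test_identical_samples_identical_columns(self):
        rng = np.random.default_rng(6)
        x = rng.exponential(500, 100)
        m = make_matrix(np.column_stack([x, x]), layer="miRNA",
                        conditions=["sensitive", "resistant"])
        out = vsn_like_normalize(m).values
        assert np.array_equal(out[:, 0], out[:, 1])

    def test_all_zero_sample_rejected(self):
        m = make_matrix(np.column_stack([np.ones(20), np.zeros(20)]),
                        layer="miRNA", conditions=["sensitive", "resistant"])
        with pytest.raises(ValueError, match="all-zero"):
            vsn_like_normalize(m)

    def test_stabilizes_variance_where_naive_log_does_not(self):
        # additive + multiplicative noise: replicate-difference sd should be
        # nearly flat across intensity quartiles after the transform
        rng = np.random.default_rng(8)
        n = 4000
        s = 2.0 ** rng.uniform(4, 14, n)
        sigma_add, sigma_mult = 50.0, 0.1
        reps = np.column_stack([
            np.maximum(s * np.exp(rng.normal(0, sigma_mult, n))
                       + rng.normal(0, sigma_add, n), 0.0)
            for _ in range(4)
        ])
        m = make_matrix(reps, layer="miRNA",
                        conditions=["sensitive", "sensitive", "resistant", "resistant"])
        out = vsn_like_normalize(m).values
        naive = np.log2(np.maximum(reps, 1.0))

        def quartile_sd_spread(mat):
            mean_raw = reps.mean(axis=1)
            qs = np.quantile(mean_raw, [0, 0.25, 0.5, 0.75, 1.0])
            sds = []
            for lo, hi in zip(qs[:-1], qs[1:]):
                sel = (mean_raw >= lo) & (mean_raw <= hi)
                sds.append(np.std(mat[sel, 0] - mat[sel, 1]))
            sds = np.array(sds)
            return (sds.max() - sds.min()) / sds.mean()

        assert quartile_sd_spread(out) < 0.25
        assert quartile_sd_spread(naive) > 2.0


class TestRankInvariant:
    def test_identical_channels_zero(self):
        rng = np.random.default_rng(9)
        ch = rng.exponential(500, 200) + 1
        out = rank_invariant_normalize(ch, ch.copy())
        assert np.median(np.abs(out)) < 1e-8

    def test_global_scaling_removed(self):
        rng = np.random.default_rng(10)
        ch = rng.exponential(500, 200) + 1
        out = rank_invariant_normalize(ch, 2.0 * ch)
        assert np.median(np.abs(out)) < 1e-8

    def test_scale_invariance_property(self):
        rng = np.random.default_rng(11)
        ch1 = rng.exponential(500, 300) + 1
        ch2 = ch1 * np.exp(rng.normal(0, 0.05, 300))
        base = rank_invariant_normalize(ch1, ch2)
        scaled = rank_invariant_normalize(3.0 * ch1, 3.0 * ch2)
        assert np.allclose(base, scaled, atol=1e-6)

    def test_intensity_dependent_bias_removed_despite_spikes(self):
        rng = np.random.default_rng(12)
        n = 2000
        ch1 = 2.0 ** rng.uniform(4, 12, n)
        A = np.log2(ch1)
        bias = 0.1 * (A - 8.0)
        ch2 = ch1 * 2.0**bias * np.exp(rng.normal(0, 0.01, n))
        spiked = rng.choice(n, size=n // 20, replace=False)
        ch2[spiked] *= 4.0
        out = rank_invariant_normalize(ch1, ch2)
        non_spiked = np.setdiff1d(np.arange(n), spiked)
        assert np.median(np.abs(out[non_spiked])) < 0.05

    def test_small_invariant_set_advises_fallback(self):
        rng = np.random.default_rng(13)
        ch1 = rng.permutation(np.arange(1.0, 51.0))
        ch2 = rng.permutation(np.arange(1.0, 51.0))
        with pytest.raises(ValueError, match="lowess"):
            rank_invariant_normalize(ch1, ch2, rank_tolerance=0.001)


class TestFilterLowSignal:
    def make(self, below_per_feature, n_arrays=5):
        n = len(below_per_feature)
        fg = np.full((n, n_arrays), 10.0)
        bg = np.full((n, n_arrays), 5.0)
        for i, k in enumerate(below_per_feature):
            fg[i, :k] = 1.0  # below background on first k arrays
        return fg, bg

    def test_boundary_exactly_60_percent_kept(self):
        fg, bg = self.make([3])  # 3 of 5 = 0.6 exactly
        report = filter_low_signal(["f0"], fg, bg, max_fraction=0.6)
        assert report.kept == {"f0"}

    def test_above_threshold_removed(self):
        fg, bg = self.make([4])  # 0.8 > 0.6
        report = filter_low_signal(["f0"], fg, bg)
        assert report.removed == {"f0"}
        assert report.below_fraction["f0"] == pytest.approx(0.8)

    def test_all_above_background_nothing_removed(self):
        fg, bg = self.make([0, 0, 0])
        report = filter_low_signal(["a", "b", "c"], fg, bg)
        assert report.removed == set()
        assert report.kept == {"a", "b", "c"}

    def test_missing_arrays_excluded_from_denominator(self):
        fg, bg = self.make([2], n_arrays=5)
        fg[0, 4] = np.nan  # feature present on 4 arrays, below on 2 -> 0.5
        report = filter_low_signal(["f0"], fg, bg)
        assert report.below_fraction["f0"] == pytest.approx(0.5)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(14)
        n = 60
        fg = rng.uniform(0, 10, size=(n, 8))
        bg = rng.uniform(0, 10, size=(n, 8))
        ids = [f"f{i}" for i in range(n)]
        removed_sets = []
        for frac in (0.9, 0.6, 0.3, 0.0):
            removed_sets.append(filter_low_signal(ids, fg, bg, frac).removed)
        for smaller, larger in zip(removed_sets[:-1], removed_sets[1:]):
            assert smaller <= larger

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            filter_low_signal(["f0"], np.ones((1, 2)), np.ones((1, 2)), max_fraction=1.5)


class TestCollapseReplicates:
    def ratio_matrix(self, values, dyes):
        # log-ratio columns: condition marks the ratio numerator (resistant)
        return make_matrix(
            values,
            conditions=["resistant"] * len(dyes),
            dyes=dyes,
        )

    def test_dye_swap_sign_flip_then_mean(self):
        m = ExpressionMatrix(
            "mRNA",
            ["f0"],
            [
                SampleMeta("t1", "resistant", 1, 1, dye="Cy5"),
                SampleMeta("t2", "resistant", 1, 2, dye="Cy3"),
            ],
            np.array([[1.0, -1.0]]),
        )
        out = collapse_replicates(m)
        assert out.values.shape == (1, 1)
        assert out.values[0, 0] == pytest.approx(1.0)

    def test_four_identical_tech_reps(self):
        m = ExpressionMatrix(
            "mRNA",
            ["f0"],
            [SampleMeta(f"t{i}", "resistant", 1, i + 1, dye="Cy5") for i in range(4)],
            np.full((1, 4), 0.5),
        )
        assert collapse_replicates(m).values[0, 0] == pytest.approx(0.5)

    def test_missing_aware_mean(self):
        vals = np.array([[0.4, 0.6, np.nan, 0.5]])
        m = ExpressionMatrix(
            "mRNA",
            ["f0"],
            [SampleMeta(f"t{i}", "resistant", 1, i + 1, dye="Cy5") for i in range(4)],
            vals,
        )
        assert collapse_replicates(m).values[0, 0] == pytest.approx(0.5)

    def test_commutes_with_feature_reordering(self):
        rng = np.random.default_rng(15)
        vals = rng.normal(size=(6, 8))
        conds = ["sensitive"] * 4 + ["resistant"] * 4
        samples = []
        for j, c in enumerate(conds):
            samples.append(SampleMeta(f"s{j}", c, 1 + j % 2, 1 + j // 2, dye="none"))
        ids = [f"f{i}" for i in range(6)]
        m = ExpressionMatrix("mRNA", ids, samples, vals)
        perm = rng.permutation(6)
        m_perm = ExpressionMatrix("mRNA", [ids[i] for i in perm], samples, vals[perm])
        a = collapse_replicates(m)
        b = collapse_replicates(m_perm)
        back = [b.feature_ids.index(f) for f in a.feature_ids]
        assert np.allclose(a.values, b.values[back])

    def test_mixed_dye_and_single_channel_group_rejected(self):
        m = ExpressionMatrix(
            "mRNA",
            ["f0"],
            [
                SampleMeta("t1", "resistant", 1, 1, dye="Cy5"),
                SampleMeta("t2", "resistant", 1, 2, dye="none"),
            ],
            np.array([[1.0, 1.0]]),
        )
        with pytest.raises(ValueError, match="mixes"):
            collapse_replicates(m)
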