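import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, special, stats

from triomics.diffexpr import (
    EBPrior,
    ModeratedTTest,
    SelectionThresholds,
    bh_fdr,
    ddct_fold_change,
    estimate_prior,
    fit_two_group,
    moderated_t,
    select_differential,
)
from tests.conftest import make_matrix


def bh_brute_force(p):
    """Independent step-up oracle: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestFitTwoGroup:
    def test_zero_variance_exact(self):
        m = make_matrix(
            [[1, 1, 1, 2, 2, 2]],
            conditions=["sensitive"] * 3 + ["resistant"] * 3,
        )
        fit = fit_two_group(m)
        assert fit["logFC"].iloc[0] == pytest.approx(1.0)
        assert fit["s2"].iloc[0] == pytest.approx(0.0)
        assert fit["df"].iloc[0] == 4

    def test_hand_computed_pooled_variance(self):
        # resistant {3,1}: var 2; sensitive {1,1}: var 0; pooled (2+0)/2 = 1
        m = make_matrix(
            [[1, 1, 3, 1]], conditions=["sensitive", "sensitive", "resistant", "resistant"]
        )
        fit = fit_two_group(m)
        assert fit["logFC"].iloc[0] == pytest.approx(1.0)
        assert fit["s2"].iloc[0] == pytest.approx(1.0)
        assert fit["df"].iloc[0] == 2

    def test_equal_groups_zero_logfc(self):
        m = make_matrix(
            [[2.5, 3.5, 2.5, 3.5]],
            conditions=["sensitive", "sensitive", "resistant", "resistant"],
        )
        assert fit_two_group(m)["logFC"].iloc[0] == pytest.approx(0.0)

    def test_insufficient_samples_flagged_not_fitted(self):
        m = make_matrix(
            [[1.0, np.nan, 2.0, 2.0], [1.0, 1.0, 2.0, 2.0]],
            conditions=["sensitive", "sensitive", "resistant", "resistant"],
        )
        fit = fit_two_group(m)
        assert not fit["tested"].iloc[0]
        assert np.isnan(fit["logFC"].iloc[0])
        assert fit["tested"].iloc[1]


class TestEstimatePrior:
    def test_recovers_scale_under_pure_sampling_noise(self):
        rng = np.random.default_rng(21)
        d = 4
        s2 = stats.chi2.rvs(d, size=5000, random_state=rng) / d  # s0_sq = 1
        prior = estimate_prior(s2, np.full(5000, d))
        assert prior.s0_sq == pytest.approx(1.0, rel=0.1)

    def test_identical_variances_give_infinite_d0(self):
        prior = estimate_prior(np.full(50, 0.3), np.full(50, 4.0))
        assert math.isinf(prior.d0)
        # scale carries the chi-square log-moment correction, same order as s2
        assert 0.2 < prior.s0_sq < 0.6

    def test_two_populations_match_moment_equation_oracle(self):
        # independent oracle: solve the digamma/trigamma moment equations
        # directly with scipy.brentq on the same sample
        rng = np.random.default_rng(22)
        d = 4
        sigma2 = np.where(np.arange(4000) % 2 == 0, 0.5, 2.0)
        s2 = sigma2 * stats.chi2.rvs(d, size=4000, random_state=rng) / d
        prior = estimate_prior(s2, np.full(4000, d))
        assert 0 < prior.d0 < math.inf

        e = np.log(s2) - special.digamma(d / 2) + np.log(d / 2)
        excess = np.var(e, ddof=1) - special.polygamma(1, d / 2)
        half_d0 = optimize.brentq(
            lambda x: special.polygamma(1, x) - excess, 1e-6, 1e6
        )
        assert prior.d0 == pytest.approx(2 * half_d0, rel=1e-6)
        s0 = np.exp(np.mean(e) + special.digamma(half_d0) - np.log(half_d0))
        assert prior.s0_sq == pytest.approx(s0, rel=1e-6)

    def test_all_zero_variances_error(self):
        with pytest.raises(ValueError):
            estimate_prior(np.zeros(20), np.full(20, 4.0))


class TestModeratedT:
    def make_fit(self, logfc, s2, df, n1=3, n2=3):
        import pandas as pd

        k = len(logfc)
        return pd.DataFrame(
            {
                "logFC": logfc,
                "avg_expr": np.zeros(k),
                "s2": s2,
                "df": df,
                "n1": np.full(k, n1),
                "n2": np.full(k, n2),
                "tested": np.full(k, True),
            },
            index=[f"f{i}" for i in range(k)],
        )

    def test_d0_zero_is_ordinary_pooled_t(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            x = rng.normal(0, 1, 3)
            y = rng.normal(0.5, 1, 3)
            t_ref, p_ref = stats.ttest_ind(y, x, equal_var=True)
            logfc = y.mean() - x.mean()
            s2 = ((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()
            fit = self.make_fit([logfc], [s2 / 4], [4])
            out = moderated_t(fit, EBPrior(d0=0.0, s0_sq=1.0))
            assert abs(out["t_mod"].iloc[0] - t_ref) < 1e-10
            assert abs(out["p"].iloc[0] - p_ref) < 1e-10

    def test_shrinkage_fixed_point_when_s2_equals_prior(self):
        fit = self.make_fit([1.0], [0.7], [4])
        base = moderated_t(fit, EBPrior(d0=0.0, s0_sq=0.7))["t_mod"].iloc[0]
        for d0 in (0.5, 2.0, 10.0, 1000.0):
            t = moderated_t(fit, EBPrior(d0=d0, s0_sq=0.7))["t_mod"].iloc[0]
            assert t == pytest.approx(base, rel=1e-12)

    def test_worked_shrinkage_case(self):
        # s0^2=1, d0=4, s2=2, df=4, logFC=1, n=3+3:
        # s~2 = (4*1 + 4*2)/8 = 1.5 ; t = 1/sqrt(1.5 * 2/3) = 1
        fit = self.make_fit([1.0], [2.0], [4])
        out = moderated_t(fit, EBPrior(d0=4.0, s0_sq=1.0))
        assert out["s_tilde_sq"].iloc[0] == pytest.approx(1.5)
        assert out["t_mod"].iloc[0] == pytest.approx(1.0)
        assert out["p"].iloc[0] == pytest.approx(2 * stats.t.sf(1.0, 8))

    def test_monotone_in_abs_logfc(self):
        fit = self.make_fit([0.1, 0.5, 1.0, 2.0], [1.0] * 4, [4.0] * 4)
        t = moderated_t(fit, EBPrior(d0=4.0, s0_sq=1.0))["t_mod"].to_numpy()
        assert np.all(np.diff(t) > 0)

    def test_large_d0_limit_matches_normal_reference(self):
        fit = self.make_fit([1.0], [2.0], [4])
        big = moderated_t(fit, EBPrior(d0=1e8, s0_sq=1.0))
        expected_t = 1.0 / math.sqrt(1.0 * (2 / 3))
        assert big["t_mod"].iloc[0] == pytest.approx(expected_t, abs=1e-6)
        inf = moderated_t(fit, EBPrior(d0=math.inf, s0_sq=1.0))
        assert inf["t_mod"].iloc[0] == pytest.approx(expected_t)
        assert inf["p"].iloc[0] == pytest.approx(2 * stats.norm.sf(expected_t))
        assert big["p"].iloc[0] == pytest.approx(inf["p"].iloc[0], abs=1e-6)


class TestBhFdr:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.03] * 10, [0.03] * 10),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.1], [0.01, 0.1]),
        ],
    )
    def test_known_cases(self, p, expected):
        assert np.allclose(bh_fdr(np.array(p)), expected)
        assert np.allclose(bh_brute_force(p), expected)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(24)
        grid = np.round(np.arange(0.0, 1.001, 0.01), 2)
        for _ in range(1000):
            n = int(rng.integers(1, 7))
            p = rng.choice(grid, size=n)
            assert np.allclose(bh_fdr(p), bh_brute_force(p), atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_permutation_invariant(self, p_list):
        p = np.array(p_list)
        q = bh_fdr(p)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)
        perm = np.random.default_rng(0).permutation(len(p))
        assert np.allclose(bh_fdr(p[perm]), q[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))


class TestSelectDifferential:
    @pytest.mark.parametrize(
        "fdr, logfc, thr, expected",
        [
            (0.009, 1.2, (0.01, 1.0), "up"),
            (0.009, 0.8, (0.01, 1.0), "ns"),
            (0.10, -0.3, (0.1, 0.0), "down"),  # boundary FDR included
            (0.011, 1.5, (0.01, 1.0), "ns"),
            (0.009, -1.0, (0.01, 1.0), "down"),  # boundary logFC included
        ],
    )
    def test_threshold_rules(self, fdr, logfc, thr, expected):
        import pandas as pd

        df = pd.DataFrame({"logFC": [logfc], "fdr": [fdr]}, index=["f0"])
        out = select_differential(df, SelectionThresholds(*thr))
        assert out["status"].iloc[0] == expected


class TestDdct:
    def test_identity(self):
        assert ddct_fold_change(20, 18, 20, 18) == pytest.approx(1.0)

    def test_worked_case_gives_fold_4(self):
        # ddCt = (20-18) - (22-18) = -2  ->  fold = 4
        assert ddct_fold_change(20, 18, 22, 18) == pytest.approx(4.0)

    def test_case_control_swap_inverts(self):
        f = ddct_fold_change(20.3, 17.9, 23.1, 18.2)
        g = ddct_fold_change(23.1, 18.2, 20.3, 17.9)
        assert f * g == pytest.approx(1.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            ddct_fold_change(np.nan, 18, 22, 18)


class TestModelInterface:
    def test_fit_summary_and_counts(self):
        rng = np.random.default_rng(25)
        X = rng.normal(0, 0.3, size=(500, 6))
        X[:20, 3:] += 3.0
        X[20:40, 3:] -= 3.0
        m = make_matrix(X, conditions=["sensitive"] * 3 + ["resistant"] * 3)
        res = ModeratedTTest(m).fit(thresholds=SelectionThresholds(0.01, 1.0))
        assert res.n_up() == 20
        assert res.n_down() == 20
        text = res.summary()
        assert "d0" in text and "up / down / ns" in text

    def test_from_dataframe_roundtrip(self):
        import pandas as pd

        rng = np.random.default_rng(26)
        df = pd.DataFrame(
            rng.normal(size=(50, 4)),
            index=[f"g{i}" for i in range(50)],
            columns=["a", "b", "c", "d"],
        )
        conditions = {"a": "sensitive", "b": "sensitive", "c": "resistant", "d": "resistant"}
        model = ModeratedTTest.from_dataframe(df, conditions)
        fitted = model.fit(prior=EBPrior(d0=0.0, s0_sq=1.0))
        assert len(fitted.frame) == 50

    def test_power_after_technical_collapse(self):
        # planted logFC 1 with technical noise sd 0.3; averaging 4 technical
        # replicates gives 3v3 columns in which nearly all planted features
        # reach FDR <= 0.01 with the correct sign
        rng = np.random.default_rng(27)
        n, n_de = 2000, 100
        tech = rng.normal(0, 0.3, size=(n, 24)).reshape(n, 6, 4).mean(axis=2)
        tech[:n_de, 3:] += 1.0
        m = make_matrix(tech, conditions=["sensitive"] * 3 + ["resistant"] * 3)
        res = ModeratedTTest(m).fit(thresholds=SelectionThresholds(0.01, 1.0))
        frame = res.frame.iloc[:n_de]
        detected = (frame["fdr"] <= 0.01) & (frame["logFC"] > 0)
        assert detected.mean() >= 0.8
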