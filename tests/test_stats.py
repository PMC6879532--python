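"""Statistical chain: gated t-tests, outlier screening, mixed ANOVA, PCA.

Where an established implementation of the same procedure exists (pingouin's
mixed ANOVA, statsmodels' varimax), it serves as an independent oracle; the
module's own results must agree with it on shared conventions.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from stmli.stats import (
    anderson_rubin_scores,
    component_mixed_anova,
    dunn_bonferroni,
    kmo_bartlett,
    levene_gated_ttest,
    mahalanobis_screen,
    mixed_anova,
    pca_varimax,
    sphericity_mauchly,
    varimax,
)


class TestLeveneGatedTTest:
    def test_identical_groups(self):
        g = np.arange(10.0)
        row = levene_gated_ttest(g, g)
        assert row.t == 0.0
        assert row.mean_difference == 0.0
        assert row.ci_low < 0 < row.ci_high

    def test_gate_selects_welch_under_heteroscedasticity(self):
        rng = np.random.default_rng(0)
        row = levene_gated_ttest(rng.normal(0, 1, 200), rng.normal(0, 6, 200))
        assert row.variant == "welch"
        assert row.levene_p < 0.05

    def test_gate_selects_pooled_under_homoscedasticity(self):
        rng = np.random.default_rng(1)
        row = levene_gated_ttest(rng.normal(0, 1, 200), rng.normal(0.5, 1, 200))
        assert row.variant == "pooled"
        assert row.df == 398

    def test_pooled_matches_scipy(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 30), rng.normal(0.3, 1, 25)
        row = levene_gated_ttest(a, b)
        ref = sps.ttest_ind(a, b, equal_var=(row.variant == "pooled"))
        assert row.t == pytest.approx(ref.statistic)
        assert row.p == pytest.approx(ref.pvalue)

    def test_ci_contains_difference(self):
        rng = np.random.default_rng(3)
        row = levene_gated_ttest(rng.normal(2, 1, 40), rng.normal(0, 1, 40))
        assert row.ci_low <= row.mean_difference <= row.ci_high

    def test_trim_applied_before_testing(self):
        a = list(range(19)) + [10_000.0]  # trim drops 0 and 10000
        b = [-10_000.0] + list(range(19))  # trim drops -10000 and 18
        row = levene_gated_ttest(a, b, trim=0.05)
        assert row.mean1 == pytest.approx(np.mean(range(1, 19)))
        assert row.mean2 == pytest.approx(np.mean(range(0, 18)))
        assert row.n1 == row.n2 == 18

    def test_degenerate_variance_error(self):
        with pytest.raises(ValueError):
            levene_gated_ttest([1.0, 1.0], [1.0, 1.0])


class TestDunnBonferroni:
    def test_m1_is_unadjusted_quantile(self):
        crit, _ = dunn_bonferroni([1.0], m=1, df=30)
        assert crit == pytest.approx(sps.t.ppf(0.975, 30))

    def test_m9_df71_matches_quantile_oracle(self):
        crit, _ = dunn_bonferroni([3.14, -3.00], m=9, df=71)
        assert crit == pytest.approx(sps.t.ppf(1 - 0.05 / 18, 71))
        # the published critical value for this family is 2.82; the direct
        # quantile at alpha/2m lands close to it
        assert crit == pytest.approx(2.82, abs=0.12)

    def test_decisions(self):
        crit, dec = dunn_bonferroni([0.5, -5.0, 1.2], m=9, df=71)
        assert dec.tolist() == [False, True, False]
        _, none_sig = dunn_bonferroni([0.1, 0.2], m=3, df=20)
        assert not none_sig.any()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            dunn_bonferroni([1.0], m=0, df=10)
        with pytest.raises(ValueError):
            dunn_bonferroni([1.0], m=2, df=0)


class TestMahalanobis:
    def test_centroid_row_retained_with_zero_distance(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal((49, 9))
        # row 0 at the mean of the others => also at the overall column means
        X2 = np.vstack([base.mean(axis=0), base])
        s = mahalanobis_screen(X2)
        assert s.distances_sq[0] < s.distances_sq[1:].min()
        assert s.retained[0]

    def test_planted_outlier_excluded(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((100, 9))
        X[7] = 10.0  # ~10 SD on every coordinate
        s = mahalanobis_screen(X, index=[f"P{i}" for i in range(100)])
        assert "P7" in s.excluded_indices

    def test_null_calibration(self):
        """Expected exclusions at p<0.001: ~0.5 per n=500 sample; the total
        over 50 replicates stays within Poisson 95% bounds of 25."""
        rng = np.random.default_rng(6)
        total = sum(
            len(mahalanobis_screen(rng.standard_normal((500, 9))).excluded_indices)
            for _ in range(50)
        )
        assert 15 <= total <= 36

    def test_singular_covariance_reported(self):
        X = np.random.default_rng(7).standard_normal((30, 4))
        X = np.hstack([X, X[:, :1]])  # duplicated column
        with pytest.raises(np.linalg.LinAlgError):
            mahalanobis_screen(X)

    def test_needs_more_rows_than_columns(self):
        with pytest.raises(ValueError):
            mahalanobis_screen(np.zeros((5, 9)))


def _to_long(Y, groups):
    n, k = Y.shape
    return pd.DataFrame(
        {
            "y": Y.ravel(),
            "subj": np.repeat(np.arange(n), k),
            "time": np.tile(np.arange(k), n),
            "grp": np.repeat(groups, k),
        }
    )


class TestMixedAnova:
    @pytest.mark.parametrize("n1,n2,k", [(12, 12, 4), (20, 7, 9), (10, 15, 3)])
    def test_matches_pingouin(self, n1, n2, k):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(n1 * 100 + k)
        Y = rng.standard_normal((n1 + n2, k)) + 0.8 * rng.standard_normal((n1 + n2, 1))
        Y[:n1] += 0.4
        groups = np.array(["a"] * n1 + ["b"] * n2)
        mine = mixed_anova(Y, groups, correction=False)
        aov = pg.mixed_anova(
            data=_to_long(Y, groups), dv="y", within="time", subject="subj", between="grp"
        )
        for row, eff in zip(aov.itertuples(), (mine.between, mine.within, mine.interaction)):
            assert eff.ss == pytest.approx(row.SS, rel=1e-9)
            assert eff.F == pytest.approx(row.F, rel=1e-9)
            assert eff.p == pytest.approx(row.p_unc, rel=1e-9)
            assert eff.partial_eta_sq == pytest.approx(row.np2, rel=1e-9)

    def test_brute_force_cell_mean_decomposition_3x3(self):
        """Sums of squares agree exactly with a loop-based cell-mean
        decomposition on a balanced 3-group x 3-level toy design."""
        rng = np.random.default_rng(8)
        n_per, k = 5, 3
        groups = np.repeat(["a", "b", "c"], n_per)
        Y = rng.standard_normal((15, k)) + np.array([0, 1, 2])[:, None].repeat(5, 0)
        rep = mixed_anova(Y, groups, correction=False)

        gm = Y.mean()
        ss_a = ss_b = ss_ab = ss_subj = ss_err = 0.0
        subj_mean = Y.mean(axis=1)
        for gi, g in enumerate(["a", "b", "c"]):
            rows = Y[groups == g]
            a_mean = rows.mean()
            ss_a += rows.size * (a_mean - gm) ** 2
            for s in range(n_per):
                ss_subj += k * (subj_mean[gi * n_per + s] - a_mean) ** 2
            for j in range(k):
                cell = rows[:, j].mean()
                b_mean = Y[:, j].mean()
                ss_ab += n_per * (cell - a_mean - b_mean + gm) ** 2
        for j in range(k):
            ss_b += Y.shape[0] * (Y[:, j].mean() - gm) ** 2
        for i in range(15):
            g = groups[i]
            for j in range(k):
                cell = Y[groups == g][:, j].mean()
                ss_err += (Y[i, j] - cell - subj_mean[i] + Y[groups == g].mean()) ** 2

        assert rep.between.ss == pytest.approx(ss_a, rel=1e-10)
        assert rep.within.ss == pytest.approx(ss_b, rel=1e-10)
        assert rep.interaction.ss == pytest.approx(ss_ab, rel=1e-10)

    def test_compound_symmetry_gives_epsilon_near_one(self):
        rng = np.random.default_rng(9)
        n, k = 200, 9
        subj = rng.standard_normal((n, 1))
        Y = subj + 0.8 * rng.standard_normal((n, k))
        groups = np.array(["a"] * 100 + ["b"] * 100)
        W, p, eps = sphericity_mauchly(Y, groups)
        assert eps > 0.95
        rep = mixed_anova(Y, groups)
        assert not rep.within.gg_adjusted

    def test_epsilon_lower_bound_on_adversarial_covariance(self):
        rng = np.random.default_rng(10)
        n, k = 40, 9
        shared = rng.standard_normal((n, 1))
        Y = shared * np.linspace(1, 10, k) + 0.01 * rng.standard_normal((n, k))
        groups = np.array(["a"] * 20 + ["b"] * 20)
        _, _, eps = sphericity_mauchly(Y, groups)
        assert 1.0 / (k - 1) <= eps <= 1.0
        assert eps < 0.3  # strongly non-spherical

    def test_gg_adjustment_applied_when_sphericity_violated(self):
        rng = np.random.default_rng(11)
        n, k = 60, 5
        shared = rng.standard_normal((n, 1))
        Y = shared * np.array([1, 1, 1, 5, 9]) + rng.standard_normal((n, k))
        groups = np.array(["a"] * 30 + ["b"] * 30)
        rep = mixed_anova(Y, groups, correction="auto")
        assert rep.mauchly_p < 0.05
        assert rep.within.gg_adjusted
        assert rep.within.df1 == pytest.approx((k - 1) * rep.gg_epsilon)

    def test_listwise_deletion_of_incomplete_rows(self):
        rng = np.random.default_rng(12)
        Y = rng.standard_normal((20, 3))
        Y[0, 1] = np.nan
        groups = np.array(["a"] * 10 + ["b"] * 10)
        with pytest.warns(UserWarning, match="dropped"):
            rep = mixed_anova(Y, groups, correction=False)
        assert rep.between.df2 == 17  # 19 subjects - 2 groups

    def test_refuses_degenerate_designs(self):
        Y = np.zeros((6, 3))
        with pytest.raises(ValueError):
            mixed_anova(Y, np.array(["a"] * 6))
        with pytest.raises(ValueError):
            mixed_anova(np.zeros((6, 1)), np.array(["a"] * 3 + ["b"] * 3))


class TestKmoBartlett:
    def test_identity_correlation_chi2_zero(self):
        kmo, chi2, df, p = kmo_bartlett(np.eye(9), 73)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert df == 36

    def test_equicorrelation_closed_form(self):
        rho, p_, n = 0.5, 9, 73
        R = np.full((p_, p_), rho)
        np.fill_diagonal(R, 1.0)
        _, chi2, df, _ = kmo_bartlett(R, n)
        logdet = np.log((1 - rho) ** (p_ - 1) * (1 + (p_ - 1) * rho))
        assert chi2 == pytest.approx(-(n - 1 - (2 * p_ + 5) / 6) * logdet, rel=1e-12)
        assert df == p_ * (p_ - 1) // 2

    def test_high_shared_variance_gives_high_kmo(self):
        rng = np.random.default_rng(13)
        f = rng.standard_normal((500, 1))
        X = f + 0.5 * rng.standard_normal((500, 9))
        kmo, *_ = kmo_bartlett(np.corrcoef(X, rowvar=False), 500)
        assert kmo > 0.85

    def test_non_positive_definite_rejected(self):
        R = np.full((3, 3), 1.0)
        with pytest.raises(np.linalg.LinAlgError):
            kmo_bartlett(R, 50)


class TestPcaVarimax:
    def _planted(self, n=500, noise=0.6, seed=14):
        rng = np.random.default_rng(seed)
        F = rng.standard_normal((n, 2))
        load = np.zeros((9, 2))
        load[:5, 0] = 0.8
        load[5:, 1] = 0.8
        X = F @ load.T + noise * rng.standard_normal((n, 9))
        return X, F, load

    def test_two_factor_recovery(self):
        X, _, load = self._planted()
        rep = pca_varimax(X, eigen_cutoff=0.80)
        assert rep.n_components == 2
        # match recovered columns to planted ones by dominant block
        L = rep.loadings
        if abs(L[:5, 0]).mean() < abs(L[:5, 1]).mean():
            L = L[:, ::-1]
        assert np.abs(L[:5, 0] - 0.8).max() < 0.1  # planted block recovered
        assert np.abs(L[5:, 1] - 0.8).max() < 0.1
        assert np.abs(L[:5, 1]).max() < 0.35  # cross block near zero
        assert np.abs(L[5:, 0]).max() < 0.35

    def test_varimax_fixed_point(self):
        L = np.zeros((6, 2))
        L[:3, 0] = 0.9
        L[3:, 1] = 0.9
        rotated = varimax(L)
        np.testing.assert_allclose(np.abs(rotated), np.abs(L), atol=1e-8)

    def test_varimax_matches_statsmodels_criterion(self):
        from statsmodels.multivariate.factor_rotation import rotate_factors

        rng = np.random.default_rng(15)
        L = rng.standard_normal((9, 3))
        crit = lambda M: ((M**2).var(axis=0)).sum()
        mine = varimax(L, normalize=False)
        ref, _ = rotate_factors(L, "varimax")
        assert crit(mine) == pytest.approx(crit(ref), rel=1e-6)

    def test_spherical_data_retains_everything_with_warning(self):
        rng = np.random.default_rng(16)
        X = rng.standard_normal((20000, 9))
        with pytest.warns(UserWarning, match="spherical"):
            rep = pca_varimax(X, eigen_cutoff=0.80)
        assert rep.n_components == 9
        np.testing.assert_allclose(rep.eigenvalues, 1.0, atol=0.07)

    def test_no_component_above_cutoff_errors(self):
        rng = np.random.default_rng(17)
        X = rng.standard_normal((5000, 9))
        with pytest.raises(ValueError, match="cutoff"):
            pca_varimax(X, eigen_cutoff=2.0)

    def test_variance_explained_reported(self):
        X, _, _ = self._planted()
        rep = pca_varimax(X)
        assert 0 < rep.variance_explained_pct < 100
        assert rep.variance_explained_pct == pytest.approx(
            rep.eigenvalues[:2].sum() / 9 * 100
        )


class TestAndersonRubin:
    def test_scores_standardized_identity_covariance(self):
        rng = np.random.default_rng(18)
        X = rng.standard_normal((300, 9)) + rng.standard_normal((300, 1))
        rep = pca_varimax(X, eigen_cutoff=0.80)
        S = anderson_rubin_scores(X, rep.loadings)
        np.testing.assert_allclose(S.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(
            np.cov(S, rowvar=False, ddof=1), np.eye(S.shape[1]), atol=1e-6
        )

    def test_recovers_planted_factors(self):
        rng = np.random.default_rng(19)
        F = rng.standard_normal((500, 2))
        load = np.zeros((9, 2))
        load[:5, 0] = 0.8
        load[5:, 1] = 0.8
        X = F @ load.T + 0.6 * rng.standard_normal((500, 9))
        rep = pca_varimax(X)
        S = anderson_rubin_scores(X, rep.loadings)
        corr = np.abs(np.corrcoef(S.T, F.T)[:2, 2:])
        assert corr.max(axis=1).min() > 0.8

    def test_single_component_is_zscored(self):
        rng = np.random.default_rng(20)
        X = rng.standard_normal((200, 4)) + 2 * rng.standard_normal((200, 1))
        rep = pca_varimax(X, eigen_cutoff=0.80)
        k1 = rep.loadings[:, :1]
        S = anderson_rubin_scores(X, k1)
        assert S.shape == (200, 1)
        assert S.mean() == pytest.approx(0.0, abs=1e-10)
        assert S.std(ddof=1) == pytest.approx(1.0, abs=1e-9)


class TestComponentAnova:
    def test_requires_two_components(self):
        with pytest.raises(ValueError):
            component_mixed_anova(np.zeros((10, 3)), np.array(["a"] * 5 + ["b"] * 5))

    def test_no_sphericity_correction_at_k2(self):
        rng = np.random.default_rng(21)
        rep = component_mixed_anova(
            rng.standard_normal((40, 2)), np.array(["a"] * 20 + ["b"] * 20)
        )
        assert rep.gg_epsilon == 1.0
        assert not rep.within.gg_adjusted

    def test_identical_groups_yield_null_between_effect(self):
        rng = np.random.default_rng(22)
        base = rng.standard_normal((20, 2))
        scores = np.vstack([base, base])
        rep = component_mixed_anova(scores, np.array(["a"] * 20 + ["b"] * 20))
        assert rep.between.F == pytest.approx(0.0, abs=1e-20)

    def test_single_component_effect_shows_as_interaction(self):
        """A group effect injected on one component only produces a larger
        interaction F than between-subject F in nearly all simulated cohorts."""
        rng = np.random.default_rng(23)
        wins = 0
        for _ in range(100):
            n = 30
            u = rng.normal(0, 0.7, 2 * n)
            c1 = u + rng.normal(0, 0.5, 2 * n)
            c2 = u + rng.normal(0, 0.5, 2 * n)
            c2[n:] += 1.5
            rep = component_mixed_anova(
                np.column_stack([c1, c2]), np.array(["a"] * n + ["b"] * n)
            )
            wins += rep.interaction.F > rep.between.F
        assert wins >= 90
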