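"""Correlation/group-comparison statistics and the outlier screen."""

import itertools

import numpy as np
import pandas as pd
import pytest

from aortaflow.cohort_stats import (
    angle_diameter_correlations,
    biomarker_correlations,
    group_summary,
    mahalanobis_screen,
    pearson_p_from_r,
    pearson_r,
    shapiro_wilk,
    spearman_r,
    ttest_from_summary,
    unpaired_ttest,
)
from aortaflow.errors import ValidationError
from aortaflow.synthetic import CohortConfig, generate_cohort


class TestPearson:
    def test_collinear_data(self):
        x = np.arange(10.0)
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-12

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson_r([1, 1, 1, 1], [1, 2, 3, 4])

    @pytest.mark.parametrize("r, n, printed", [
        (0.536, 18, 0.022),   # jet angle vs AAO size, BAV group
        (0.562, 28, 0.002),   # jet angle vs STJ size, pooled
        (0.405, 28, 0.033),   # jet angle vs SOV size, pooled
        (0.472, 18, 0.048),   # jet angle vs STJ size, BAV group
        (0.386, 18, 0.114),   # jet angle vs SOV size, BAV group
    ])
    def test_published_r_n_p_triples(self, r, n, printed):
        assert round(pearson_p_from_r(r, n), 3) == printed

    def test_strong_pooled_correlation_below_printed_bound(self):
        assert pearson_p_from_r(0.645, 28) < 0.001

    def test_null_r_gives_p_one(self):
        assert pearson_p_from_r(0.0, 10) == pytest.approx(1.0)

    def test_unit_r_convention(self):
        with pytest.warns(UserWarning):
            assert pearson_p_from_r(1.0, 5) == 0.0

    def test_matches_scipy_reference(self, rng):
        from scipy import stats
        x, y = rng.normal(size=(2, 40))
        r, p = pearson_r(x, y)
        ref = stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


class TestSpearman:
    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        rho1, _ = spearman_r(x, y)
        rho2, _ = spearman_r(np.exp(x), y**3)
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_strictly_monotone_pairing_is_one(self):
        rho, _ = spearman_r([1, 5, 9, 11], [2, 4, 100, 101])
        assert rho == pytest.approx(1.0)

    def test_hand_computed_small_case(self):
        rho, _ = spearman_r([1, 2, 3], [3, 1, 2])
        assert rho == pytest.approx(-0.5)

    def test_midrank_tie_handling(self):
        from scipy.stats import rankdata
        np.testing.assert_allclose(rankdata([1, 1, 2], method="average"),
                                   [1.5, 1.5, 3])
        rho, _ = spearman_r([1, 1, 2, 3], [4, 4, 5, 6])
        assert rho == pytest.approx(1.0)

    def test_exact_permutation_p_matches_brute_force(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        rho, p = spearman_r(x, y, exact=True)
        # independent brute force over all rank permutations
        ry = np.argsort(np.argsort(y)).astype(float)
        rx = np.arange(5.0)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        hits = sum(abs(np.corrcoef(rx, list(perm))[0, 1]) >= obs - 1e-12
                   for perm in itertools.permutations(ry))
        assert p == pytest.approx(hits / 120.0)
        assert rho == pytest.approx(np.corrcoef(rx, ry)[0, 1])


class TestTTests:
    def test_identical_groups(self):
        t, df, p = unpaired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        t, df, p = unpaired_ttest([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == 4
        assert p == pytest.approx(0.0214, abs=2e-3)

    def test_degenerate_zero_variance_conventions(self):
        t, _, p = unpaired_ttest([2.0, 2.0], [5.0, 5.0])
        assert np.isinf(t) and p == 0.0

    def test_summary_variant_matches_raw_data(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 9)
        t_raw, _, p_raw = unpaired_ttest(a, b)
        t_sum, _, p_sum = ttest_from_summary(
            a.mean(), a.std(ddof=1) / np.sqrt(a.size), a.size,
            b.mean(), b.std(ddof=1) / np.sqrt(b.size), b.size)
        assert t_sum == pytest.approx(t_raw, abs=1e-9)
        assert p_sum == pytest.approx(p_raw, abs=1e-12)

    def test_published_angle_group_comparison(self):
        # BAV 17.54+/-0.87 (n=18) vs control 10.01+/-1.29 (n=10), SEM scale
        _, df, p = ttest_from_summary(17.54, 0.87, 18, 10.01, 1.29, 10)
        assert df == 26
        assert p <= 0.01

    def test_published_aao_group_comparison(self):
        _, _, p = ttest_from_summary(23.31, 0.78, 18, 17.15, 0.65, 10)
        assert p < 0.001


class TestShapiroWilk:
    def test_large_normal_sample_not_rejected(self, rng):
        w, p = shapiro_wilk(rng.normal(size=500))
        assert w > 0.99
        assert p > 0.01

    def test_power_against_exponential(self):
        rejections = sum(
            shapiro_wilk(np.random.default_rng(s).exponential(size=50))[1] < 0.05
            for s in range(100))
        assert rejections >= 95

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            shapiro_wilk([3.0, 3.0, 3.0, 3.0])


class TestMahalanobisScreen:
    def test_univariate_reduces_to_squared_z(self, rng):
        x = rng.normal(size=30)
        out = mahalanobis_screen(x[:, None], alpha=0.025)
        z2 = ((x - x.mean()) / x.std(ddof=1)) ** 2
        np.testing.assert_allclose(out["d2"], z2, rtol=1e-9)

    def test_identity_covariance_is_euclidean(self, rng):
        # build data with exactly identity sample covariance
        X = rng.normal(size=(200, 2))
        X = (X - X.mean(0)) @ np.linalg.inv(np.linalg.cholesky(np.cov(X.T, ddof=1)).T)
        out = mahalanobis_screen(X)
        np.testing.assert_allclose(out["d2"], (X - X.mean(0)).pow(2).sum(1)
                                   if hasattr(X, "pow") else ((X - X.mean(0)) ** 2).sum(1),
                                   rtol=1e-6)

    def test_planted_outlier_is_flagged_and_kept(self, rng):
        X = rng.normal(size=(50, 2))
        X[0] = (10.0, 10.0)
        out = mahalanobis_screen(X, alpha=0.025)
        assert bool(out.loc[0, "flagged"])
        assert out["flagged"].sum() == 1
        assert len(out) == 50  # flags reported, rows never dropped

    def test_singular_covariance_rejected(self):
        X = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValidationError):
            mahalanobis_screen(X)


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(CohortConfig(seed=11))


class TestCohortTables:

    def test_group_summary_shape_and_significance(self, cohort):
        tbl = group_summary(cohort)
        assert set(tbl["variable"]) == {
            "diam_aov_adj", "diam_sov_adj", "diam_stj_adj", "diam_aao_adj",
            "flow_angle_deg"}
        angle = tbl.set_index("variable").loc["flow_angle_deg"]
        assert angle["n_bav"] == 18 and angle["n_control"] == 10
        assert angle["mean_bav"] > angle["mean_control"]

    def test_too_small_group_rejected(self, cohort):
        small = pd.concat([cohort[cohort["group"] == "BAV"],
                           cohort[cohort["group"] == "control"].head(2)])
        with pytest.raises(ValidationError):
            group_summary(small)

    def test_correlation_table_covers_levels(self, cohort):
        tbl = angle_diameter_correlations(cohort)
        assert list(tbl["level"]) == ["AOV", "SOV", "STJ", "AAO"]
        assert (tbl["n"] == 28).all()

    def test_biomarkers_restricted_to_bav_pairwise_complete(self, cohort):
        tbl = biomarker_correlations(cohort)
        assert (tbl["n"] <= 18).all()
        assert {"mmp2", "mmp9", "timp1", "timp2"} == set(tbl["biomarker"])


class TestParameterRecovery:
    def test_large_sample_recovers_target_r(self):
        cfg = CohortConfig(n_bav=1286, n_control=714, seed=5)
        df = generate_cohort(cfg)
        r, _ = pearson_r(df["flow_angle_deg"], df["diam_aao_adj"])
        assert r == pytest.approx(0.645, abs=0.05)

    def test_fisher_z_interval_covers_at_study_size(self):
        """At n=28 the Fisher-z 95% CI for the AAO correlation covers the
        generative target in about 95% of seeds."""
        target = np.arctanh(0.645)
        covered = 0
        n_seeds = 300
        for s in range(n_seeds):
            df = generate_cohort(CohortConfig(seed=s))
            r, _ = pearson_r(df["flow_angle_deg"], df["diam_aao_adj"])
            z = np.arctanh(r)
            half = 1.96 / np.sqrt(28 - 3)
            covered += z - half <= target <= z + half
        assert 0.90 <= covered / n_seeds <= 0.99
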