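"""OLS core, nested F, residual-bootstrap p-values, and the cohort screen."""

import numpy as np
import pytest
from scipy import stats

from mircohort import (
    AssociationScreen,
    ResidualBootstrapF,
    ValidationError,
    bootstrap_f_pvalue,
    f_statistic,
    fit_ols,
)
from mircohort.association import RankDeficiencyError
from mircohort.preprocess import categorize_cohort, filter_detectable, log2_transform, normalize_75th


class TestFitOLS:
    def test_exact_line(self):
        x = np.arange(5.0)
        design = np.column_stack([np.ones(5), x])
        fit = fit_ols(2 * x + 1, design)
        np.testing.assert_allclose(fit.params, [1.0, 2.0], atol=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_intercept_only_is_mean(self, rng):
        y = rng.normal(3, 1, size=20)
        fit = fit_ols(y, np.ones((20, 1)))
        assert fit.params[0] == pytest.approx(y.mean())

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        X = np.column_stack([np.ones(50), rng.standard_normal((50, 3))])
        y = X @ [1, 0.5, -0.2, 0.1] + rng.standard_normal(50)
        fit = fit_ols(y, X)
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.params, ref.params, rtol=1e-10)
        assert fit.rss == pytest.approx(ref.ssr)

    def test_collinear_column_named(self, rng):
        x = rng.standard_normal(30)
        design = np.column_stack([np.ones(30), x, 2 * x])
        with pytest.raises(RankDeficiencyError, match="double"):
            fit_ols(rng.standard_normal(30), design,
                    column_names=["const", "x", "double"])


class TestFStatistic:
    def test_zero_column_addition_is_rank_error(self, rng):
        X = np.column_stack([np.ones(20), rng.standard_normal(20)])
        full = np.column_stack([X, np.zeros(20)])
        with pytest.raises(RankDeficiencyError):
            fit_ols(rng.standard_normal(20), full)

    def test_null_mean_matches_f_distribution(self, rng):
        """Under H0 the statistic's average is near df_den / (df_den - 2)."""
        n, reps = 40, 4000
        X_null = np.ones((n, 1))
        x = rng.standard_normal(n)
        X_full = np.column_stack([X_null, x])
        stats_ = []
        for _ in range(reps):
            y = rng.standard_normal(n)
            stats_.append(f_statistic(fit_ols(y, X_full), fit_ols(y, X_null)))
        expected = (n - 2) / (n - 4)
        assert np.mean(stats_) == pytest.approx(expected, rel=0.1)

    def test_perfect_fit_gives_extreme_f(self):
        # RSS of the full model collapses to numerical zero, so the
        # statistic blows up (infinite up to floating-point roundoff)
        x = np.arange(6.0)
        full = np.column_stack([np.ones(6), x])
        f = f_statistic(fit_ols(2 * x, full), fit_ols(2 * x, np.ones((6, 1))))
        assert f > 1e12


class TestBootstrapF:
    def _designs(self, rng, n=60):
        x = rng.standard_normal(n)
        null = np.column_stack([np.ones(n), rng.standard_normal(n)])
        return np.column_stack([x, null]), null

    def test_add_one_floor(self, rng):
        full, null = self._designs(rng)
        y = full[:, 0] * 5 + rng.standard_normal(60) * 0.01
        p, f = bootstrap_f_pvalue(y, full, null, n_boot=99, seed=1)
        assert p == pytest.approx(1 / 100)

    def test_single_replicate_can_give_p_one(self, rng):
        full, null = self._designs(rng)
        y = rng.standard_normal(60)  # null outcome: F_1 >= F_obs happens often
        ps = [bootstrap_f_pvalue(y, full, null, n_boot=1, seed=s)[0]
              for s in range(20)]
        assert set(ps) <= {0.5, 1.0} and 1.0 in ps

    def test_p_in_valid_range(self, rng):
        full, null = self._designs(rng)
        for _ in range(5):
            y = rng.standard_normal(60)
            p, _ = bootstrap_f_pvalue(y, full, null, n_boot=200, seed=rng)
            assert 1 / 201 <= p <= 1.0

    def test_tracks_exact_f_under_gaussian_null(self, rng):
        """Oracle equivalence at moderate B on one Gaussian dataset."""
        n = 200
        full, null = self._designs(rng, n)
        y = rng.standard_normal(n)
        res = ResidualBootstrapF(y, full, null).fit(n_boot=4000, seed=7)
        assert abs(res.p_boot - res.p_exact_f) < 0.03

    def test_deterministic_given_seed(self, rng):
        full, null = self._designs(rng)
        y = rng.standard_normal(60)
        p1, _ = bootstrap_f_pvalue(y, full, null, n_boot=500, seed=11)
        p2, _ = bootstrap_f_pvalue(y, full, null, n_boot=500, seed=11)
        assert p1 == p2


@pytest.fixture(scope="module")
def screen_inputs(small_cohort):
    normed, _ = normalize_75th(small_cohort.mirna_normal)
    kept, _ = filter_detectable(normed)
    log2 = log2_transform(kept)
    levels = categorize_cohort(small_cohort.exposures, small_cohort.subjects,
                               "ltc_wine")
    return log2, levels


class TestAssociationScreen:
    def test_planted_features_trend_negative(self, small_cohort, screen_inputs):
        log2, levels = screen_inputs
        res = AssociationScreen.from_records(
            log2, small_cohort.subjects, levels, exposure_variable="ltc_wine"
        ).fit(n_boot=300, seed=3)
        planted = set(small_cohort.planted_exposure_features) & set(res.frame["feature_id"])
        sub = res.frame[res.frame["feature_id"].isin(planted)]
        assert (sub["beta_std"] < 0).mean() >= 0.95

    def test_invariant_to_sample_order(self, small_cohort, screen_inputs):
        log2, levels = screen_inputs
        perm = np.random.default_rng(0).permutation(log2.n_samples)
        shuffled = type(log2)(
            log2.feature_ids,
            [log2.sample_ids[j] for j in perm],
            log2.values[:, perm],
            log2.tissue, log2.assay, log2.scale,
        )
        subjects = list(reversed(small_cohort.subjects))
        a = AssociationScreen.from_records(
            log2, small_cohort.subjects, levels).fit(n_boot=100, seed=5)
        b = AssociationScreen.from_records(
            shuffled, subjects, levels).fit(n_boot=100, seed=5)
        np.testing.assert_allclose(a.frame["p_boot"], b.frame["p_boot"])
        np.testing.assert_allclose(a.frame["beta"], b.frame["beta"])

    def test_two_indicator_coding_has_two_df(self, small_cohort, screen_inputs):
        log2, levels = screen_inputs
        res = AssociationScreen.from_records(
            log2, small_cohort.subjects, levels, coding="two_indicator"
        ).fit(n_boot=50, seed=2)
        assert (res.frame["df_num"] == 2).all()

    def test_non_log2_matrix_rejected(self, small_cohort):
        with pytest.raises(ValidationError, match="log2"):
            AssociationScreen.from_records(
                small_cohort.mirna_normal, small_cohort.subjects, {})
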