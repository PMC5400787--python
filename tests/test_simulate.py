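"""Generator determinism, marginal structure, and parameter recovery."""

import numpy as np
import pytest

from mircohort import (
    SimulationConfig,
    ValidationError,
    simulate_cohort,
    simulate_expression,
    simulate_subjects,
)
from mircohort.preprocess import categorize_cohort, filter_detectable, log2_transform, normalize_75th
from mircohort.simulate import BeverageModel


class TestSimulateSubjects:
    def test_same_seed_identical_cohorts(self):
        cfg = SimulationConfig(n_subjects=100, seed=1)
        s1, e1 = simulate_subjects(cfg)
        s2, e2 = simulate_subjects(cfg)
        assert [x.age_dx for x in s1] == [x.age_dx for x in s2]
        assert [p.grams_per_day for p in e1] == [p.grams_per_day for p in e2]

    def test_age_marginal(self):
        cfg = SimulationConfig(n_subjects=2000, seed=2)
        subjects, _ = simulate_subjects(cfg)
        ages = np.array([s.age_dx for s in subjects])
        assert abs(ages.mean() - 64) < 1.0
        assert ages.min() >= 30 and ages.max() <= 79

    def test_total_is_sum_of_beverages(self):
        cfg = SimulationConfig(n_subjects=200, seed=3)
        _, exposures = simulate_subjects(cfg)
        for p in exposures:
            for tp in ("referent", "y10", "y20"):
                total = p.gday("total", tp)
                parts = sum(p.gday(b, tp) for b in ("beer", "wine", "liquor"))
                assert total == pytest.approx(parts, abs=1e-12)

    def test_full_wine_zero_inflation_forces_no_wine_high(self):
        cfg = SimulationConfig(n_subjects=300, seed=4)
        cfg.beverages["wine"] = BeverageModel(p_zero=1.0, gamma_shape=1.0,
                                              gamma_mean=20.0)
        subjects, exposures = simulate_subjects(cfg)
        levels = categorize_cohort(exposures, subjects, "ltc_wine")
        # nobody drinks wine, so nobody can reach the sex-specific cutoff
        assert 2 not in set(levels.values())

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(n_subjects=5)
        with pytest.raises(ValidationError):
            SimulationConfig(sigma_log2=0.0)


class TestSimulateExpression:
    def test_subject_exposure_mismatch_rejected(self):
        cfg = SimulationConfig(n_subjects=20, n_mirna=10, n_mrna=5, seed=5)
        subjects, exposures = simulate_subjects(cfg)
        with pytest.raises(ValidationError):
            simulate_expression(subjects, exposures[:-1], cfg)

    def test_unit_distortion_gives_unit_scaling_factors(self):
        cfg = SimulationConfig(n_subjects=40, n_mirna=300, n_mrna=5,
                               distortion_range=(1.0, 1.0), subject_sd=0.0,
                               covariate_effects={}, frac_low_features=0.0,
                               missing_rate=0.0, seed=6)
        cohort = simulate_cohort(cfg)
        _, fac = normalize_75th(cohort.mirna_normal)
        factors = np.array(list(fac.per_sample.values()))
        # no distortion and no sample-level signal: factors stay near 1
        assert np.all(np.abs(np.log(factors)) < 0.35)
        assert np.median(np.abs(np.log(factors))) < 0.1

    def test_slope_recovery_at_half_sd_per_level(self):
        """Planted trend of 0.5 residual-SD/level is recovered by
        covariate-adjusted OLS on the generator's log2 signal."""
        from mircohort.association import build_design, fit_ols
        from mircohort.datatypes import subjects_to_frame
        from mircohort.simulate import simulate_subjects

        cfg = SimulationConfig(n_subjects=500, n_mirna=200, n_mrna=5,
                               beta_exposure=0.5, seed=7)
        subjects, exposures = simulate_subjects(cfg)
        expr = simulate_expression(subjects, exposures, cfg)
        levels = categorize_cohort(exposures, subjects, "ltc_wine")
        ids, X_full, _, _, _, _ = build_design(subjects_to_frame(subjects), levels)
        pos = {s.subject_id: j for j, s in enumerate(subjects)}
        cols = [pos[i] for i in ids]
        planted = set(expr.truth.loc[expr.truth["role"] == "exposure_effect",
                                     "feature_id"])
        betas = [
            fit_ols(expr.mirna_normal_log2[i][cols], X_full).params[0]
            for i, f in enumerate(expr.mirna_normal.feature_ids) if f in planted
        ]
        resid_sd = np.hypot(cfg.sigma_log2, cfg.subject_sd)
        assert np.mean(betas) / resid_sd == pytest.approx(0.5, abs=0.05)

    def test_low_abundance_features_fail_detectability(self):
        cfg = SimulationConfig(n_subjects=100, n_mirna=100, n_mrna=5,
                               frac_low_features=0.1, seed=8)
        cohort = simulate_cohort(cfg)
        normed, _ = normalize_75th(cohort.mirna_normal)
        _, excluded = filter_detectable(normed)
        low = set(cohort.truth.loc[cohort.truth["role"] == "low_abundance",
                                   "feature_id"])
        assert low <= set(excluded)


class TestSimulateSurvival:
    def test_zero_censoring_all_events(self):
        cfg = SimulationConfig(n_subjects=100, n_mirna=20, n_mrna=5,
                               censor_rate=0.0, seed=9)
        cohort = simulate_cohort(cfg)
        assert all(s.event for s in cohort.subjects)

    def test_censor_rate_roughly_respected(self):
        cfg = SimulationConfig(n_subjects=1000, n_mirna=20, n_mrna=5,
                               censor_rate=0.5, log_hr_per_sd=0.0, seed=10)
        cohort = simulate_cohort(cfg)
        frac_censored = np.mean([not s.event for s in cohort.subjects])
        assert 0.35 <= frac_censored <= 0.65

    def test_cox_recovers_planted_log_hr(self):
        """Fitting the planted covariate itself (generator log2 signal)
        recovers the planted log hazard ratio per SD."""
        from mircohort import fit_cox
        from mircohort.simulate import simulate_subjects, simulate_survival

        cfg = SimulationConfig(n_subjects=1000, n_mirna=20, n_mrna=5,
                               log_hr_per_sd=float(np.log(1.5)),
                               censor_rate=0.3, n_planted_survival=1,
                               frac_planted_exposure=0.0, seed=11)
        subjects, exposures = simulate_subjects(cfg)
        expr = simulate_expression(subjects, exposures, cfg)
        subjects = simulate_survival(subjects, expr.mirna_normal_log2, cfg,
                                     planted=[0])
        t = np.array([s.survival_time for s in subjects])
        ev = np.array([s.event for s in subjects])
        stage = np.array([float(s.ajcc_stage) for s in subjects])
        x = expr.mirna_normal_log2[0]
        z = (x - x.mean()) / x.std()
        fit = fit_cox(t, ev, np.column_stack([stage, z]))
        assert fit.params[-1] == pytest.approx(np.log(1.5), abs=0.1)

    def test_full_cohort_deterministic(self):
        cfg = SimulationConfig(n_subjects=60, n_mirna=30, n_mrna=10, seed=12)
        c1, c2 = simulate_cohort(cfg), simulate_cohort(cfg)
        np.testing.assert_array_equal(c1.mirna_normal.values, c2.mirna_normal.values,
                                      strict=True)
        np.testing.assert_array_equal(c1.mrna_tumor.values, c2.mrna_tumor.values)
        assert [s.survival_time for s in c1.subjects] == \
            [s.survival_time for s in c2.subjects]
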