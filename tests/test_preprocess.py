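"""Normalization, filtering, transforms and exposure categorization."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from mircohort import (
    ExposureProfile,
    ExpressionMatrix,
    Scale,
    ValidationError,
    categorize_exposure,
    filter_detectable,
    log2_transform,
    normalize_75th,
    standardize_feature,
)


def _matrix(values, scale="raw"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        [f"f{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        values, "normal", "mirna", scale,
    )


class TestNormalize75th:
    def test_identical_samples_give_unit_factors(self):
        x = _matrix(np.tile([[1.0], [2.0], [3.0], [4.0]], (1, 3)))
        normed, fac = normalize_75th(x)
        assert all(abs(f - 1) < 1e-12 for f in fac.per_sample.values())
        np.testing.assert_allclose(normed.values, x.values)

    def test_hand_computed_factors(self):
        # per-sample q75 of {1,2,3,4} is 3.25; columns scaled by 16/13 and
        # 4 give q75 of 4 and 13 -> reference median 8.5
        col = np.array([1.0, 2.0, 3.0, 4.0])
        x = _matrix(np.column_stack([col * 16 / 13, col * 4]))
        normed, fac = normalize_75th(x)
        assert fac.reference == pytest.approx(8.5)
        assert fac.per_sample["s0"] == pytest.approx(8.5 / 4.0)
        assert fac.per_sample["s1"] == pytest.approx(8.5 / 13.0)
        for j in range(2):
            assert np.nanquantile(normed.values[:, j], 0.75) == pytest.approx(8.5, abs=1e-9)

    def test_two_sample_reference_is_median_of_q75(self):
        # constant columns: q75 = {4, 16} -> reference 10, factors {2.5, 0.625}
        x = _matrix(np.array([[4.0, 16.0]] * 5))
        _, fac = normalize_75th(x)
        assert fac.reference == pytest.approx(10.0)
        assert fac.per_sample["s0"] == pytest.approx(2.5)
        assert fac.per_sample["s1"] == pytest.approx(0.625)

    def test_all_zero_sample_errors_with_name(self):
        x = _matrix(np.array([[1.0, 0.0], [2.0, 0.0]]))
        with pytest.raises(ValidationError, match="s1"):
            normalize_75th(x)

    def test_idempotent(self, rng):
        x = _matrix(np.exp(rng.normal(3, 1, size=(40, 12))))
        normed, _ = normalize_75th(x)
        again, fac2 = normalize_75th(dataclasses.replace(normed, scale=Scale.RAW))
        np.testing.assert_allclose(again.values, normed.values, atol=1e-9)

    def test_missing_cells_stay_missing(self):
        vals = np.array([[1.0, 2.0], [np.nan, 3.0], [4.0, 5.0], [6.0, 7.0]])
        normed, _ = normalize_75th(_matrix(vals))
        assert np.isnan(normed.values[1, 0]) and not np.isnan(normed.values[1, 1])


class TestFilterDetectable:
    def _det_matrix(self, n_detect, n_samples=100):
        vals = np.zeros((1, n_samples))
        vals[0, :n_detect] = 5.0
        return _matrix(vals, scale="normalized")

    def test_19_of_100_excluded(self):
        _, excluded = filter_detectable(self._det_matrix(19))
        assert excluded == ["f0"]

    def test_20_of_100_retained_boundary_inclusive(self):
        kept, excluded = filter_detectable(self._det_matrix(20))
        assert kept.feature_ids == ["f0"] and excluded == []

    def test_fully_detectable_identity(self, rng):
        x = _matrix(rng.uniform(1, 10, size=(30, 20)), scale="normalized")
        kept, excluded = filter_detectable(x)
        assert kept.feature_ids == x.feature_ids and not excluded

    def test_monotone_in_threshold(self, rng):
        vals = rng.uniform(0, 1, size=(50, 40))
        vals[vals < 0.4] = 0.0
        x = _matrix(vals, scale="normalized")
        kept_loose = set(filter_detectable(x, 0.3)[0].feature_ids)
        kept_tight = set(filter_detectable(x, 0.7)[0].feature_ids)
        assert kept_tight <= kept_loose


class TestLog2Transform:
    @pytest.mark.parametrize("raw,offset,expected", [
        (8.0, 0.0, 3.0), (1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (7.0, 1.0, 3.0),
    ])
    def test_values(self, raw, offset, expected):
        x = _matrix([[raw, raw]], scale="normalized")
        out = log2_transform(x, offset=offset)
        assert out.values[0, 0] == pytest.approx(expected)
        assert out.scale == Scale.LOG2


class TestStandardizeFeature:
    def test_three_point_inverse_normal(self):
        out = standardize_feature(np.array([5.0, 1.0, 9.0]))
        expected = stats.norm.ppf([0.5, 1 / 6, 5 / 6])
        np.testing.assert_allclose(out, expected, atol=1e-12)
        assert out[2] == pytest.approx(0.9674, abs=1e-4)

    def test_symmetric_input_symmetric_output(self):
        out = standardize_feature(np.array([-3.0, -1.0, 0.0, 1.0, 3.0]))
        np.testing.assert_allclose(out, -out[::-1], atol=1e-12)

    def test_mean_near_zero_and_missing_propagates(self, rng):
        v = rng.normal(10, 2, size=200)
        v[5] = np.nan
        out = standardize_feature(v)
        assert np.isnan(out[5])
        assert abs(np.nanmean(out)) < 1e-6

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            standardize_feature(np.array([2.0, 2.0, 2.0]))

    def test_zscore_alternative(self, rng):
        v = rng.normal(0, 3, size=50)
        out = standardize_feature(v, method="zscore")
        assert np.std(out, ddof=1) == pytest.approx(1.0)


def _profile(gday_each_tp, drinks_month=30.0, any_fh=True):
    gpd = {}
    for tp in ("referent", "y10", "y20"):
        gpd[("wine", tp)] = gday_each_tp
        gpd[("beer", tp)] = 0.0
        gpd[("liquor", tp)] = 0.0
        gpd[("total", tp)] = gday_each_tp
    return ExposureProfile("S1", gpd, drinks_per_month_longterm=drinks_month,
                           any_fh_alcohol_referent=any_fh)


class TestCategorizeExposure:
    def test_male_25_gday_is_high(self):
        cat = categorize_exposure(_profile(25.0), "male", "ltc_wine")
        assert cat.level_name == "high"

    def test_female_9_gday_is_moderate(self):
        cat = categorize_exposure(_profile(9.0), "female", "ltc_wine")
        assert cat.level_name == "moderate"

    def test_female_10_gday_boundary_is_high(self):
        cat = categorize_exposure(_profile(10.0), "female", "ltc_wine")
        assert cat.level_name == "high"

    def test_abstainer_is_none(self):
        cat = categorize_exposure(_profile(0.0, drinks_month=0.0, any_fh=False),
                                  "male", "ltc_total")
        assert cat.level_name == "none"

    def test_food_history_drinking_blocks_none(self):
        cat = categorize_exposure(_profile(0.0, drinks_month=0.0, any_fh=True),
                                  "male", "ltc_total")
        assert cat.level_name == "moderate"

    def test_lt_uses_only_recall_timepoints(self):
        gpd = {("wine", tp): g for tp, g in
               [("referent", 100.0), ("y10", 5.0), ("y20", 5.0)]}
        for tp, g in [("referent", 100.0), ("y10", 5.0), ("y20", 5.0)]:
            gpd[("beer", tp)] = 0.0
            gpd[("liquor", tp)] = 0.0
            gpd[("total", tp)] = g
        p = ExposureProfile("S1", gpd, drinks_per_month_longterm=12,
                            any_fh_alcohol_referent=True)
        assert categorize_exposure(p, "male", "lt_wine").level_name == "moderate"
        assert categorize_exposure(p, "male", "ltc_wine").level_name == "high"

    def test_missing_timepoint_named(self):
        gpd = {("wine", "referent"): 5.0, ("wine", "y10"): 5.0}
        p = ExposureProfile("S1", gpd, drinks_per_month_longterm=12,
                            any_fh_alcohol_referent=True)
        with pytest.raises(ValidationError, match="y20"):
            categorize_exposure(p, "male", "ltc_wine")

    def test_monotone_in_gday(self):
        levels = [categorize_exposure(_profile(g), "female", "ltc_wine").level
                  for g in (0.5, 3.0, 9.9, 10.0, 40.0)]
        assert levels == sorted(levels)
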