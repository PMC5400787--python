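"""Array normalization, detectability filtering, transforms and exposure coding.

Normalization follows the 75th-percentile scaling scheme used for Agilent
total-gene-signal data: every sample is multiplied by a factor equal to the
median of all samples' 75th percentiles divided by that sample's own 75th
percentile, so that after scaling every sample shares the same 75th
percentile.  Percentiles use linear interpolation between order statistics
(numpy's default, R's type 7); the convention is configurable because the
choice is not canonical across array software.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import (
    ExposureCategory,
    ExposureProfile,
    ExpressionMatrix,
    Scale,
    Sex,
    ValidationError,
    EXPOSURE_VARIABLES,
    LEVEL_HIGH,
    LEVEL_MODERATE,
    LEVEL_NONE,
)

#: Sex-specific g/day cutoffs separating moderate from high consumption.
HIGH_CUTOFF_GDAY = {Sex.MALE: 20.0, Sex.FEMALE: 10.0}


@dataclass
class ScalingFactors:
    """Per-sample multiplicative factors and the shared reference percentile."""

    per_sample: dict[str, float]
    reference: float


def _sample_q75(col: np.ndarray, method: str) -> float:
    vals = col[~np.isnan(col)]
    if vals.size == 0:
        return np.nan
    return float(np.quantile(vals, 0.75, method=method))


def normalize_75th(
    x: ExpressionMatrix, method: str = "linear"
) -> tuple[ExpressionMatrix, ScalingFactors]:
    """Scale each sample so all 75th percentiles equal their median.

    Parameters
    ----------
    x : raw-scale expression matrix; every sample needs at least one
        non-missing positive value.
    method : percentile interpolation convention passed to ``np.quantile``
        ("linear" = type 7).

    Returns the normalized matrix plus the factors, where
    ``factor[s] = reference / q75(s)`` and ``reference`` is the median of the
    per-sample 75th percentiles.  Missing cells stay missing.
    """
    if x.scale != Scale.RAW:
        raise ValidationError(f"normalize_75th expects raw scale, got {x.scale.value!r}")
    q75 = np.array([_sample_q75(x.values[:, j], method) for j in range(x.n_samples)])
    bad = [x.sample_ids[j] for j in range(x.n_samples)
           if np.isnan(q75[j]) or q75[j] <= 0]
    if bad:
        raise ValidationError(
            "sample(s) with non-positive or undefined 75th percentile: " + ", ".join(bad)
        )
    reference = float(np.median(q75))
    factors = reference / q75
    out = dataclasses.replace(
        x, values=x.values * factors[np.newaxis, :], scale=Scale.NORMALIZED
    )
    return out, ScalingFactors(
        per_sample=dict(zip(x.sample_ids, factors.tolist())), reference=reference
    )


def filter_detectable(
    x: ExpressionMatrix, min_frac: float = 0.20
) -> tuple[ExpressionMatrix, list[str]]:
    """Keep features detectable (non-missing and > 0) in >= ``min_frac`` of samples.

    The boundary is inclusive: a feature detectable in exactly 20% of samples
    survives the default filter.  Feature order is preserved.
    """
    if not 0 < min_frac <= 1:
        raise ValidationError(f"min_frac must be in (0, 1], got {min_frac}")
    detectable = (~np.isnan(x.values)) & (x.values > 0)
    frac = detectable.sum(axis=1) / x.n_samples
    keep_mask = frac >= min_frac - 1e-12
    kept = [f for f, k in zip(x.feature_ids, keep_mask) if k]
    excluded = [f for f, k in zip(x.feature_ids, keep_mask) if not k]
    return x.subset_features(kept), excluded


def log2_transform(x: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Elementwise log2(value + offset); the offset guards against zeros.

    With the default offset 1, a raw zero maps to log2 value 0.  Negative
    inputs are rejected (they would indicate an un-normalized or corrupted
    matrix).
    """
    vals = x.values
    if np.nanmin(vals, initial=0.0) < 0:
        raise ValidationError("log2_transform: negative values present")
    if offset <= 0 and np.nanmin(vals, initial=np.inf) <= 0:
        raise ValidationError("log2_transform: zero values with non-positive offset")
    return dataclasses.replace(x, values=np.log2(vals + offset), scale=Scale.LOG2)


def standardize_feature(values: np.ndarray, method: str = "inverse_normal") -> np.ndarray:
    """Map a feature's values onto a standard-normal scale.

    ``inverse_normal`` (default) is the rank-based inverse-normal transform:
    each value becomes the standard-normal quantile of (rank - 0.5) / n,
    with ties receiving average ranks and n counting non-missing values.
    ``zscore`` subtracts the mean and divides by the (ddof=1) SD.  Missing
    entries propagate as NaN.
    """
    v = np.asarray(values, dtype=float)
    mask = ~np.isnan(v)
    obs = v[mask]
    if obs.size < 2 or np.ptp(obs) == 0:
        raise ValidationError(
            "standardize_feature needs >=2 non-missing values with nonzero variance"
        )
    out = np.full_like(v, np.nan)
    if method == "inverse_normal":
        ranks = stats.rankdata(obs, method="average")
        out[mask] = stats.norm.ppf((ranks - 0.5) / obs.size)
    elif method == "zscore":
        out[mask] = (obs - obs.mean()) / obs.std(ddof=1)
    else:
        raise ValueError(f"unknown standardization method {method!r}")
    return out


#: Recall timepoints combined by each exposure family: long-term (LT) uses
#: the 10- and 20-year recalls; long-term-plus-current (LTC) adds the
#: 2-year referent period.
_VARIABLE_TIMEPOINTS = {"lt": ("y10", "y20"), "ltc": ("referent", "y10", "y20")}


def categorize_exposure(
    profile: ExposureProfile, sex: Sex | str, variable: str
) -> ExposureCategory:
    """Classify one subject's consumption for one of the 8 alcohol variables.

    Level "none" requires both fewer than one drink per month on the
    long-term questionnaire and no alcoholic beverages on the food-history
    questionnaire.  Anyone else is "moderate" or "high" according to the
    mean g/day over the variable's timepoints against the sex-specific
    cutoff (male 20 g/day, female 10 g/day; at-or-above means high).
    """
    if variable not in EXPOSURE_VARIABLES:
        raise ValidationError(
            f"unknown exposure variable {variable!r}; expected one of {EXPOSURE_VARIABLES}"
        )
    sex = Sex(sex)
    family, beverage = variable.split("_", 1)
    timepoints = _VARIABLE_TIMEPOINTS[family]
    gdays = []
    for tp in timepoints:
        g = profile.gday(beverage, tp)
        if np.isnan(g):
            raise ValidationError(
                f"subject {profile.subject_id!r}: missing {beverage} g/day at "
                f"timepoint {tp!r} needed for {variable!r}"
            )
        gdays.append(g)
    if profile.drinks_per_month_longterm < 1 and not profile.any_fh_alcohol_referent:
        level = LEVEL_NONE
    else:
        mean_gday = float(np.mean(gdays))
        cutoff = HIGH_CUTOFF_GDAY[sex]
        level = LEVEL_HIGH if mean_gday >= cutoff else LEVEL_MODERATE
    return ExposureCategory(subject_id=profile.subject_id, variable=variable, level=level)


def categorize_cohort(
    profiles, subjects, variable: str
) -> dict[str, int]:
    """Exposure level per subject id for one variable, aligning by id."""
    sex_by_id = {s.subject_id: s.sex for s in subjects}
    out = {}
    for p in profiles:
        if p.subject_id not in sex_by_id:
            continue
        out[p.subject_id] = categorize_exposure(p, sex_by_id[p.subject_id], variable).level
    return out


def paired_difference(
    tumor: ExpressionMatrix, normal: ExpressionMatrix
) -> ExpressionMatrix:
    """Per-subject tumor-minus-normal difference of log2 expression.

    Restricted to subjects present in both matrices and to the shared
    feature set; cells missing in either tissue are missing in the output.
    """
    if tumor.scale != Scale.LOG2 or normal.scale != Scale.LOG2:
        raise ValidationError("paired_difference expects log2-scale matrices")
    shared_samples = [s for s in tumor.sample_ids if s in set(normal.sample_ids)]
    shared_features = [f for f in tumor.feature_ids if f in set(normal.feature_ids)]
    if not shared_samples:
        raise ValidationError("no shared subjects between tumor and normal matrices")
    t = tumor.subset_features(shared_features).subset_samples(shared_samples)
    n = normal.subset_features(shared_features).subset_samples(shared_samples)
    n_df = n.to_frame().loc[t.feature_ids, t.sample_ids]
    return ExpressionMatrix(
        feature_ids=t.feature_ids,
        sample_ids=t.sample_ids,
        values=t.values - n_df.to_numpy(),
        tissue=tumor.tissue,
        assay=tumor.assay,
        scale=Scale.LOG2,
    )
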