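"""Shared data containers for the expression / exposure / survival pipeline.

The pipeline moves three kinds of tabular data around: expression matrices
(features x samples, one per tissue/assay combination), per-subject clinical
records, and per-subject alcohol-exposure profiles.  All three are plain
dataclasses wrapping numpy / pandas structures, with validation at
construction time so that malformed inputs fail at the boundary rather than
deep inside a screen.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when a container or file violates a structural invariant."""


class FormatError(ValueError):
    """Raised when an input file cannot be parsed into the expected shape."""


class Tissue(str, enum.Enum):
    TUMOR = "tumor"
    NORMAL = "normal"


class Assay(str, enum.Enum):
    MIRNA = "mirna"
    MRNA = "mrna"


class Scale(str, enum.Enum):
    RAW = "raw"
    NORMALIZED = "normalized"
    LOG2 = "log2"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Center(str, enum.Enum):
    KAISER = "kaiser"
    UTAH = "utah"


class Site(str, enum.Enum):
    COLON = "colon"
    RECTAL = "rectal"


#: The eight alcohol exposure variables: long-term (10- and 20-year recall)
#: and long-term-plus-current (adds the referent period), for total intake
#: and each beverage.
EXPOSURE_VARIABLES = (
    "lt_total", "ltc_total",
    "lt_beer", "ltc_beer",
    "lt_wine", "ltc_wine",
    "lt_liquor", "ltc_liquor",
)

BEVERAGES = ("beer", "wine", "liquor", "total")
TIMEPOINTS = ("referent", "y10", "y20")

#: Ordinal consumption levels.
LEVEL_NONE, LEVEL_MODERATE, LEVEL_HIGH = 0, 1, 2
LEVEL_NAMES = {0: "none", 1: "moderate", 2: "high"}


@dataclass
class ExpressionMatrix:
    """A features x samples expression matrix tagged by tissue and assay.

    ``values`` may contain NaN (missing / undetected cells).  On the raw and
    normalized scales all non-missing values must be non-negative; the log2
    scale is unrestricted.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    tissue: Tissue
    assay: Assay
    scale: Scale = Scale.RAW

    def __post_init__(self) -> None:
        self.tissue = Tissue(self.tissue)
        self.assay = Assay(self.assay)
        self.scale = Scale(self.scale)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        for name, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            if dupes:
                raise FormatError(f"duplicate {name} id(s): {', '.join(map(str, dupes))}")
        if self.scale in (Scale.RAW, Scale.NORMALIZED):
            bad = np.argwhere(np.nan_to_num(self.values, nan=0.0) < 0)
            if bad.size:
                r, c = bad[0]
                raise ValidationError(
                    f"negative value {self.values[r, c]!r} at feature "
                    f"{self.feature_ids[r]!r}, sample {self.sample_ids[c]!r} "
                    f"on scale {self.scale.value!r}"
                )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def feature(self, feature_id: str) -> np.ndarray:
        try:
            i = self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"feature {feature_id!r} not in matrix") from None
        return self.values[i]

    def subset_features(self, keep: Sequence[str]) -> "ExpressionMatrix":
        keep_set = set(keep)
        idx = [i for i, f in enumerate(self.feature_ids) if f in keep_set]
        return replace(
            self,
            feature_ids=[self.feature_ids[i] for i in idx],
            values=self.values[idx, :],
        )

    def subset_samples(self, keep: Sequence[str]) -> "ExpressionMatrix":
        keep_set = set(keep)
        idx = [j for j, s in enumerate(self.sample_ids) if s in keep_set]
        return replace(
            self,
            sample_ids=[self.sample_ids[j] for j in idx],
            values=self.values[:, idx],
        )


@dataclass
class SubjectRecord:
    """Clinical covariates, stage and follow-up for one subject."""

    subject_id: str
    age_dx: float
    sex: Sex
    center: Center
    smoking_current: bool
    site: Site
    ajcc_stage: int
    survival_time: float | None = None
    event: bool | None = None

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        self.center = Center(self.center)
        self.site = Site(self.site)
        self.ajcc_stage = int(self.ajcc_stage)
        if not 1 <= self.ajcc_stage <= 4:
            raise ValidationError(
                f"subject {self.subject_id!r}: AJCC stage {self.ajcc_stage} not in 1..4"
            )
        if self.survival_time is not None:
            if self.survival_time < 0:
                raise ValidationError(
                    f"subject {self.subject_id!r}: negative survival_time "
                    f"{self.survival_time}"
                )
            if self.event is None:
                raise ValidationError(
                    f"subject {self.subject_id!r}: survival_time set but event missing"
                )


@dataclass
class ExposureProfile:
    """Beverage-specific ethanol intake (g/day) at three recall timepoints.

    ``grams_per_day`` maps (beverage, timepoint) -> ethanol g/day, with
    beverage in {beer, wine, liquor, total} and timepoint in
    {referent, y10, y20}.  The total at each timepoint must equal the sum of
    the three beverages.
    """

    subject_id: str
    grams_per_day: Mapping[tuple[str, str], float]
    drinks_per_month_longterm: float = 0.0
    any_fh_alcohol_referent: bool = False

    def __post_init__(self) -> None:
        self.grams_per_day = dict(self.grams_per_day)
        if self.drinks_per_month_longterm < 0:
            raise ValidationError(
                f"subject {self.subject_id!r}: negative drinks_per_month_longterm"
            )
        for (bev, tp), v in self.grams_per_day.items():
            if bev not in BEVERAGES or tp not in TIMEPOINTS:
                raise ValidationError(f"unknown beverage/timepoint key {(bev, tp)!r}")
            if not np.isnan(v) and v < 0:
                raise ValidationError(
                    f"subject {self.subject_id!r}: negative g/day for {(bev, tp)!r}"
                )
        for tp in TIMEPOINTS:
            parts = [self.grams_per_day.get((b, tp), np.nan) for b in ("beer", "wine", "liquor")]
            total = self.grams_per_day.get(("total", tp), np.nan)
            if not any(np.isnan(p) for p in parts) and not np.isnan(total):
                if abs(total - sum(parts)) > 1e-9:
                    raise ValidationError(
                        f"subject {self.subject_id!r}: total g/day at {tp!r} "
                        f"({total}) != beer+wine+liquor ({sum(parts)})"
                    )

    def gday(self, beverage: str, timepoint: str) -> float:
        return float(self.grams_per_day.get((beverage, timepoint), np.nan))


@dataclass
class ExposureCategory:
    """Ordinal alcohol-consumption level for one subject and one variable."""

    subject_id: str
    variable: str
    level: int

    def __post_init__(self) -> None:
        if self.variable not in EXPOSURE_VARIABLES:
            raise ValidationError(
                f"unknown exposure variable {self.variable!r}; "
                f"expected one of {EXPOSURE_VARIABLES}"
            )
        if self.level not in (0, 1, 2):
            raise ValidationError(f"level must be 0, 1 or 2, got {self.level!r}")

    @property
    def level_name(self) -> str:
        return LEVEL_NAMES[self.level]


def subjects_to_frame(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    """One row per subject, enums rendered as their string values."""
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "age_dx": [s.age_dx for s in subjects],
            "sex": [s.sex.value for s in subjects],
            "center": [s.center.value for s in subjects],
            "smoking_current": [int(s.smoking_current) for s in subjects],
            "site": [s.site.value for s in subjects],
            "ajcc_stage": [s.ajcc_stage for s in subjects],
            "survival_time": [np.nan if s.survival_time is None else s.survival_time for s in subjects],
            "event": [np.nan if s.event is None else int(s.event) for s in subjects],
        }
    ).set_index("subject_id", drop=False)
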