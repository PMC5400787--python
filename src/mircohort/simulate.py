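"""Synthetic colorectal-cohort generator.

Generates subjects, beverage-specific alcohol-exposure profiles, paired
tumor/normal miRNA expression, normal-mucosa mRNA expression and censored
survival with the statistical structure the downstream screens assume:

* log-normal expression — log2 signal is baseline + shared subject intercept
  (inducing tumor/normal pairing and inter-feature correlation) + covariate
  terms + Gaussian noise;
* a planted subset of miRNAs carries a linear trend across the three ordinal
  levels of one alcohol variable, with slope ``beta_exposure`` expressed in
  residual-SD units per level;
* a planted subset carries a log-linear hazard effect per SD of expression;
* raw-scale matrices include a per-sample multiplicative distortion (drawn
  log-uniformly from a configurable range) so the 75th-percentile
  normalization has real work to do, and a block of low-abundance features
  is mostly undetected so the 20% detectability filter has real work to do.

Alcohol intake uses a Gaussian-copula zero-inflated gamma: a per-subject
drinker propensity correlates abstention across beverages, and a shared
latent factor correlates intake across the referent/10-year/20-year recall
timepoints (rho ~ 0.7).  One drink is converted as 13 g ethanol.

Everything is deterministic given ``SimulationConfig.seed``; the three
stages draw from independent child streams of that seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    Assay,
    Center,
    ExposureProfile,
    ExpressionMatrix,
    Scale,
    Sex,
    Site,
    SubjectRecord,
    ValidationError,
    BEVERAGES,
    TIMEPOINTS,
)
from .preprocess import categorize_exposure

GRAMS_PER_DRINK = 13.0
DAYS_PER_MONTH = 30.4


@dataclass
class BeverageModel:
    """Zero-inflated gamma marginal for one beverage's g/day intake."""

    p_zero: float
    gamma_shape: float
    gamma_mean: float


#: Default beverage marginals: roughly a third of the cohort abstains
#: entirely (abstention is strongly correlated across beverages through the
#: drinker-propensity factor), and drinkers average 15-22 g ethanol/day per
#: beverage consumed, with an exponential right tail.  Together these give
#: each ordinal exposure variable a roughly balanced none/moderate/high
#: split rather than a degenerate one.
DEFAULT_BEVERAGES = {
    "beer": BeverageModel(p_zero=0.55, gamma_shape=1.0, gamma_mean=18.0),
    "wine": BeverageModel(p_zero=0.40, gamma_shape=1.0, gamma_mean=22.0),
    "liquor": BeverageModel(p_zero=0.60, gamma_shape=1.0, gamma_mean=15.0),
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults mirror the study conditions.

    ``beta_exposure`` is the planted trend in residual-SD units per ordinal
    exposure level; ``log_hr_per_sd`` the planted log hazard ratio per SD of
    expression.  ``censor_rate`` is the approximate fraction of follow-up
    censored before death.
    """

    n_subjects: int = 555
    n_mirna: int = 800
    n_mrna: int = 500
    frac_planted_exposure: float = 0.10
    beta_exposure: float = -0.2
    exposure_variable: str = "ltc_wine"
    covariate_effects: dict = dc_field(default_factory=lambda: {
        "age_dx": 0.004, "sex_female": 0.10, "center_utah": 0.05,
        "smoking_current": 0.15,
    })
    sigma_log2: float = 1.0
    subject_sd: float = 0.5
    tumor_offset_sd: float = 0.8
    beta_exposure_diff: float = 0.0
    frac_low_features: float = 0.08
    detect_prob_low: float = 0.10
    missing_rate: float = 0.01
    distortion_range: tuple = (0.5, 2.0)
    planted_survival_mirnas: list | None = None
    n_planted_survival: int = 2
    log_hr_per_sd: float = float(np.log(1.2))
    censor_rate: float = 0.5
    baseline_hazard: float = 2.5e-4
    stage_effect: float = float(np.log(1.4))
    site: str = "rectal"
    frac_rectal: float = 0.5
    frac_male: float = 0.55
    frac_kaiser: float = 0.65
    frac_smoking: float = 0.20
    stage_probs: tuple = (0.20, 0.35, 0.30, 0.15)
    beverages: dict = dc_field(default_factory=lambda: dict(DEFAULT_BEVERAGES))
    rho_timepoints: float = 0.7
    rho_drinker: float = 0.8
    frac_mrna_coupled: float = 0.05
    mrna_coupling: float = 0.5
    mrna_target_mirna: int | None = None
    mrna_tumor_offset_sd: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_planted_exposure", "censor_rate", "frac_low_features",
                     "detect_prob_low", "missing_rate", "frac_male", "frac_kaiser",
                     "frac_smoking", "frac_rectal", "frac_mrna_coupled"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.n_subjects < 10:
            raise ValidationError("n_subjects must be >= 10")
        if self.sigma_log2 <= 0:
            raise ValidationError("sigma_log2 must be > 0")
        if abs(sum(self.stage_probs) - 1) > 1e-9:
            raise ValidationError("stage_probs must sum to 1")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))
        )


def _zero_inflated_gamma(rng, model: BeverageModel, n: int, n_tp: int,
                         rho_tp: float, drinker_latent: np.ndarray,
                         rho_drinker: float) -> np.ndarray:
    """(n, n_tp) g/day draws, correlated across timepoints and with the
    subject's overall drinker propensity via a Gaussian copula."""
    shared = rng.standard_normal(n)
    eps = rng.standard_normal((n, n_tp))
    z_tp = np.sqrt(rho_tp) * shared[:, None] + np.sqrt(1 - rho_tp) * eps
    z = np.sqrt(rho_drinker) * drinker_latent[:, None] + \
        np.sqrt(1 - rho_drinker) * z_tp
    u = stats.norm.cdf(z)
    out = np.zeros((n, n_tp))
    drink = u >= model.p_zero
    u_pos = (u[drink] - model.p_zero) / (1 - model.p_zero)
    u_pos = np.clip(u_pos, 1e-12, 1 - 1e-12)
    scale = model.gamma_mean / model.gamma_shape
    out[drink] = stats.gamma.ppf(u_pos, a=model.gamma_shape, scale=scale)
    return out


def simulate_subjects(cfg: SimulationConfig) -> tuple[list[SubjectRecord], list[ExposureProfile]]:
    """Draw the cohort's clinical records and alcohol-exposure profiles.

    Ages are Normal(64, 10) truncated to [30, 79]; sex, center, smoking,
    site and stage follow the configured marginals.  Survival fields are
    left unset until :func:`simulate_survival`.
    """
    rng = cfg.rng(0)
    n = cfg.n_subjects
    ids = [f"S{i:05d}" for i in range(n)]
    # latent Normal(66.5, 10) truncated to the 30-79 eligibility window has
    # mean ~64.5 and SD ~9, matching the cohort's age-at-diagnosis marginal
    a, b = (30 - 66.5) / 10, (79 - 66.5) / 10
    ages = stats.truncnorm.rvs(a, b, loc=66.5, scale=10, size=n, random_state=rng)
    male = rng.random(n) < cfg.frac_male
    kaiser = rng.random(n) < cfg.frac_kaiser
    smoking = rng.random(n) < cfg.frac_smoking
    if cfg.site == "mixed":
        rectal = rng.random(n) < cfg.frac_rectal
    elif cfg.site in ("rectal", "colon"):
        rectal = np.full(n, cfg.site == "rectal")
    else:
        raise ValidationError(f"site must be 'rectal', 'colon' or 'mixed', got {cfg.site!r}")
    stages = rng.choice([1, 2, 3, 4], size=n, p=cfg.stage_probs)

    drinker_latent = rng.standard_normal(n)
    gday = {}
    for bev in ("beer", "wine", "liquor"):
        gday[bev] = _zero_inflated_gamma(
            rng, cfg.beverages[bev], n, len(TIMEPOINTS),
            cfg.rho_timepoints, drinker_latent, cfg.rho_drinker,
        )
    total = gday["beer"] + gday["wine"] + gday["liquor"]

    subjects, profiles = [], []
    for i in range(n):
        subjects.append(SubjectRecord(
            subject_id=ids[i], age_dx=float(ages[i]),
            sex=Sex.MALE if male[i] else Sex.FEMALE,
            center=Center.KAISER if kaiser[i] else Center.UTAH,
            smoking_current=bool(smoking[i]),
            site=Site.RECTAL if rectal[i] else Site.COLON,
            ajcc_stage=int(stages[i]),
        ))
        gpd = {}
        for bev in ("beer", "wine", "liquor"):
            for j, tp in enumerate(TIMEPOINTS):
                gpd[(bev, tp)] = float(gday[bev][i, j])
        for j, tp in enumerate(TIMEPOINTS):
            gpd[("total", tp)] = float(total[i, j])
        longterm_gday = float(total[i, 1:].mean())  # y10 + y20 recall
        profiles.append(ExposureProfile(
            subject_id=ids[i],
            grams_per_day=gpd,
            drinks_per_month_longterm=longterm_gday / GRAMS_PER_DRINK * DAYS_PER_MONTH,
            any_fh_alcohol_referent=bool(total[i, 0] > 0),
        ))
    return subjects, profiles


@dataclass
class SyntheticExpression:
    mirna_normal: ExpressionMatrix
    mirna_tumor: ExpressionMatrix
    mrna_normal: ExpressionMatrix
    mrna_tumor: ExpressionMatrix
    truth: pd.DataFrame
    #: distortion-free log2 signal of the normal miRNA matrix, used to plant
    #: survival effects on the true biological scale
    mirna_normal_log2: np.ndarray = dc_field(default=None, repr=False)


def _covariate_term(subjects: list[SubjectRecord], effects: dict) -> np.ndarray:
    n = len(subjects)
    term = np.zeros(n)
    for i, s in enumerate(subjects):
        term[i] = (
            effects.get("age_dx", 0.0) * (s.age_dx - 64.0)
            + effects.get("sex_female", 0.0) * (s.sex == Sex.FEMALE)
            + effects.get("center_utah", 0.0) * (s.center == Center.UTAH)
            + effects.get("smoking_current", 0.0) * s.smoking_current
        )
    return term


def _to_raw(log2_signal: np.ndarray, rng, cfg: SimulationConfig,
            low_mask: np.ndarray) -> np.ndarray:
    lo, hi = cfg.distortion_range
    distortion = np.exp(rng.uniform(np.log(lo), np.log(hi), size=log2_signal.shape[1]))
    raw = np.exp2(log2_signal) * distortion[np.newaxis, :]
    # low-abundance features are mostly below the detection floor
    if low_mask.any():
        undetected = rng.random(raw.shape) >= cfg.detect_prob_low
        raw[low_mask] = np.where(undetected[low_mask], np.nan, raw[low_mask])
    if cfg.missing_rate > 0:
        raw[rng.random(raw.shape) < cfg.missing_rate] = np.nan
    return raw


def simulate_expression(subjects, exposures, cfg: SimulationConfig) -> SyntheticExpression:
    """Generate paired tumor/normal miRNA and tumor/normal mRNA matrices.

    Returns raw-scale matrices (with per-sample distortion and missingness)
    plus a truth table listing each planted feature's role and effect.
    """
    if len(subjects) != len(exposures):
        raise ValidationError(
            f"{len(subjects)} subjects but {len(exposures)} exposure profiles"
        )
    order = {s.subject_id for s in subjects}
    if {e.subject_id for e in exposures} != order:
        raise ValidationError("subject ids of subjects and exposures differ")
    rng = cfg.rng(1)
    n = len(subjects)
    ids = [s.subject_id for s in subjects]
    exp_by_id = {e.subject_id: e for e in exposures}
    levels = np.array([
        categorize_exposure(exp_by_id[s.subject_id], s.sex, cfg.exposure_variable).level
        for s in subjects
    ], dtype=float)

    subj_intercept = cfg.subject_sd * rng.standard_normal(n)
    cov_term = _covariate_term(subjects, cfg.covariate_effects)
    resid_sd = float(np.hypot(cfg.sigma_log2, cfg.subject_sd))

    # --- miRNA ---
    m = cfg.n_mirna
    n_low = int(round(cfg.frac_low_features * m))
    baseline = rng.uniform(5.0, 11.0, size=m)
    low_idx = rng.choice(m, size=n_low, replace=False)
    low_mask = np.zeros(m, dtype=bool)
    low_mask[low_idx] = True
    baseline[low_mask] = rng.uniform(0.5, 2.0, size=n_low)
    loading = rng.uniform(0.5, 1.5, size=m)

    n_planted = int(round(cfg.frac_planted_exposure * m))
    eligible = np.flatnonzero(~low_mask)
    planted_exposure = rng.choice(eligible, size=n_planted, replace=False) \
        if n_planted else np.array([], dtype=int)
    beta_log2 = np.zeros(m)
    beta_log2[planted_exposure] = cfg.beta_exposure * resid_sd
    beta_diff_log2 = np.zeros(m)
    if cfg.beta_exposure_diff:
        beta_diff_log2[planted_exposure] = cfg.beta_exposure_diff * resid_sd

    shared = (loading[:, None] * (subj_intercept + cov_term)[None, :]
              + beta_log2[:, None] * levels[None, :])
    normal_log2 = (baseline[:, None] + shared
                   + cfg.sigma_log2 * rng.standard_normal((m, n)))
    tumor_offset = cfg.tumor_offset_sd * rng.standard_normal(m)
    tumor_log2 = (baseline[:, None] + tumor_offset[:, None] + shared
                  + beta_diff_log2[:, None] * levels[None, :]
                  + cfg.sigma_log2 * rng.standard_normal((m, n)))
    mirna_ids = [f"mir-{i:04d}" for i in range(m)]

    # --- mRNA, a subset linearly coupled to one miRNA's normal expression ---
    g = cfg.n_mrna
    g_base = rng.uniform(5.0, 11.0, size=g)
    g_loading = rng.uniform(0.5, 1.5, size=g)
    target = cfg.mrna_target_mirna
    if target is None:
        target = int(planted_exposure[0]) if n_planted else 0
    n_coupled = int(round(cfg.frac_mrna_coupled * g))
    coupled = rng.choice(g, size=n_coupled, replace=False) if n_coupled else np.array([], dtype=int)
    coupling = np.zeros(g)
    if n_coupled:
        signs = np.where(np.arange(n_coupled) % 2 == 0, -1.0, 1.0)
        coupling[coupled] = signs * cfg.mrna_coupling
    target_centered = normal_log2[target] - np.nanmean(normal_log2[target])
    g_shared = g_loading[:, None] * (subj_intercept + cov_term)[None, :]
    mrna_normal_log2 = (g_base[:, None] + g_shared
                        + coupling[:, None] * target_centered[None, :]
                        + cfg.sigma_log2 * rng.standard_normal((g, n)))
    g_tumor_offset = cfg.mrna_tumor_offset_sd * rng.standard_normal(g)
    mrna_tumor_log2 = (mrna_normal_log2 + g_tumor_offset[:, None]
                       + 0.5 * cfg.sigma_log2 * rng.standard_normal((g, n)))
    mrna_ids = [f"gene-{i:04d}" for i in range(g)]

    no_low = np.zeros(g, dtype=bool)
    expr = SyntheticExpression(
        mirna_normal=ExpressionMatrix(mirna_ids, ids, _to_raw(normal_log2, rng, cfg, low_mask),
                                      "normal", Assay.MIRNA, Scale.RAW),
        mirna_tumor=ExpressionMatrix(mirna_ids, ids, _to_raw(tumor_log2, rng, cfg, low_mask),
                                     "tumor", Assay.MIRNA, Scale.RAW),
        mrna_normal=ExpressionMatrix(mrna_ids, ids, _to_raw(mrna_normal_log2, rng, cfg, no_low),
                                     "normal", Assay.MRNA, Scale.RAW),
        mrna_tumor=ExpressionMatrix(mrna_ids, ids, _to_raw(mrna_tumor_log2, rng, cfg, no_low),
                                    "tumor", Assay.MRNA, Scale.RAW),
        truth=_truth_table(cfg, mirna_ids, mrna_ids, planted_exposure, beta_log2,
                           low_mask, target, coupled, coupling, g_tumor_offset),
        mirna_normal_log2=normal_log2,
    )
    return expr


def _truth_table(cfg, mirna_ids, mrna_ids, planted_exposure, beta_log2, low_mask,
                 target, coupled, coupling, g_tumor_offset) -> pd.DataFrame:
    rows = []
    for i in planted_exposure:
        rows.append({"feature_id": mirna_ids[i], "kind": "mirna",
                     "role": "exposure_effect", "value": beta_log2[i]})
    for i in np.flatnonzero(low_mask):
        rows.append({"feature_id": mirna_ids[i], "kind": "mirna",
                     "role": "low_abundance", "value": cfg.detect_prob_low})
    rows.append({"feature_id": mirna_ids[target], "kind": "mirna",
                 "role": "mrna_coupling_target", "value": np.nan})
    for j in coupled:
        rows.append({"feature_id": mrna_ids[j], "kind": "mrna",
                     "role": "coupled_mrna", "value": coupling[j]})
        rows.append({"feature_id": mrna_ids[j], "kind": "mrna",
                     "role": "tumor_log2_offset", "value": g_tumor_offset[j]})
    return pd.DataFrame(rows, columns=["feature_id", "kind", "role", "value"])


def simulate_survival(subjects: list[SubjectRecord],
                      normal_mirna_log2: np.ndarray | ExpressionMatrix,
                      cfg: SimulationConfig,
                      planted: list[int] | None = None) -> list[SubjectRecord]:
    """Attach exponential event times with expression-linked hazards.

    log hazard = log(baseline) + log_hr_per_sd * z(planted expression summed)
    + stage_effect * (stage - 1); censoring is exponential with rate set so
    roughly ``censor_rate`` of subjects are censored.  Returns new records.
    """
    rng = cfg.rng(2)
    values = (normal_mirna_log2.values if isinstance(normal_mirna_log2, ExpressionMatrix)
              else np.asarray(normal_mirna_log2, dtype=float))
    n = len(subjects)
    if values.shape[1] != n:
        raise ValidationError("expression matrix columns must match subjects")
    if planted is None:
        planted = cfg.planted_survival_mirnas
    if planted is None:
        planted = list(range(min(cfg.n_planted_survival, values.shape[0])))
    lin = np.zeros(n)
    for i in planted:
        x = values[i]
        x = np.where(np.isnan(x), np.nanmean(x), x)
        lin += cfg.log_hr_per_sd * (x - x.mean()) / x.std(ddof=0)
    stages = np.array([s.ajcc_stage for s in subjects], dtype=float)
    rate = cfg.baseline_hazard * np.exp(lin + cfg.stage_effect * (stages - 1))
    t_event = rng.exponential(1.0 / rate)
    if cfg.censor_rate > 0:
        c_rate = cfg.baseline_hazard * np.exp(cfg.stage_effect) \
            * cfg.censor_rate / (1 - cfg.censor_rate)
        t_censor = rng.exponential(1.0 / c_rate, size=n)
    else:
        t_censor = np.full(n, np.inf)
    t_obs = np.minimum(t_event, t_censor)
    event = t_event <= t_censor
    return [
        dataclasses.replace(s, survival_time=float(t_obs[i]), event=bool(event[i]))
        for i, s in enumerate(subjects)
    ]


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    subjects: list[SubjectRecord]
    exposures: list[ExposureProfile]
    mirna_normal: ExpressionMatrix
    mirna_tumor: ExpressionMatrix
    mrna_normal: ExpressionMatrix
    mrna_tumor: ExpressionMatrix
    truth: pd.DataFrame

    @property
    def planted_exposure_features(self) -> list[str]:
        t = self.truth
        return t.loc[(t["role"] == "exposure_effect"), "feature_id"].tolist()


def simulate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    """Run all three generator stages; fully deterministic given cfg.seed."""
    subjects, exposures = simulate_subjects(cfg)
    expr = simulate_expression(subjects, exposures, cfg)
    # survival is tied to the planted exposure set so that the
    # exposure -> mortality -> mRNA narrative is exercisable end to end
    planted_ids = expr.truth.loc[expr.truth["role"] == "exposure_effect", "feature_id"]
    id_to_idx = {f: i for i, f in enumerate(expr.mirna_normal.feature_ids)}
    planted = cfg.planted_survival_mirnas
    if planted is None:
        planted = [id_to_idx[f] for f in planted_ids.head(cfg.n_planted_survival)]
        if not planted:
            planted = list(range(min(cfg.n_planted_survival, cfg.n_mirna)))
    subjects = simulate_survival(subjects, expr.mirna_normal_log2, cfg, planted=planted)
    truth = expr.truth.copy()
    surv_rows = pd.DataFrame({
        "feature_id": [expr.mirna_normal.feature_ids[i] for i in planted],
        "kind": "mirna", "role": "survival_effect", "value": cfg.log_hr_per_sd,
    })
    truth = pd.concat([truth, surv_rows], ignore_index=True)
    return SyntheticCohort(
        config=cfg, subjects=subjects, exposures=exposures,
        mirna_normal=expr.mirna_normal, mirna_tumor=expr.mirna_tumor,
        mrna_normal=expr.mrna_normal, mrna_tumor=expr.mrna_tumor, truth=truth,
    )
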