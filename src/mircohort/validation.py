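"""Simulation studies validating the pipeline's statistical operating
characteristics.

Each function runs a self-contained Monte-Carlo experiment against known
generator truth — normalization exactness, agreement of the residual
bootstrap with the exact F test under Gaussian errors, type-I error,
positive-FDR calibration, permutation-LRT agreement with its chi-square
asymptotics, Cox effect recovery, and end-to-end recovery of planted
exposure effects — and returns the measured quantities.  The test suite and
the reproduction script both call these.

Problem sizes are chosen so the full battery runs in minutes on one core:
bootstrap and permutation resampling are vectorised or solver-accelerated,
and replicate counts follow the sizes quoted in the docstrings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import AssociationScreen, ResidualBootstrapF
from .datatypes import ExpressionMatrix, Scale
from .preprocess import categorize_cohort, filter_detectable, log2_transform, normalize_75th
from .qvalue import apply_gate, estimate_pi0, qvalues
from .simulate import SimulationConfig, simulate_cohort
from .survival import PermutationCoxLRT, fit_cox


def _child(seed: int, k: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(k,)))


# ---------------------------------------------------------------------------
# normalization


def normalization_exactness(n_matrices: int = 100, seed: int = 0) -> dict:
    """Max deviation of post-normalization 75th percentiles from the
    reference, and the max change from applying normalization twice,
    over random log-normal matrices with missing cells."""
    worst_dev = 0.0
    worst_idem = 0.0
    for k in range(n_matrices):
        rng = _child(seed, k)
        n_feat = int(rng.integers(30, 120))
        n_samp = int(rng.integers(8, 40))
        vals = np.exp(rng.normal(5, 1.5, size=(n_feat, n_samp))
                      + rng.normal(0, 0.5, size=(1, n_samp)))
        vals[rng.random(vals.shape) < 0.05] = np.nan
        x = ExpressionMatrix([f"f{i}" for i in range(n_feat)],
                             [f"s{j}" for j in range(n_samp)],
                             vals, "normal", "mirna", "raw")
        normed, fac = normalize_75th(x)
        q75 = np.array([np.nanquantile(normed.values[:, j], 0.75)
                        for j in range(n_samp)])
        worst_dev = max(worst_dev, float(np.max(np.abs(q75 - fac.reference))))
        again, fac2 = normalize_75th(dataclasses.replace(normed, scale=Scale.RAW))
        worst_idem = max(worst_idem, float(np.nanmax(np.abs(again.values - normed.values))))
    return {"max_q75_deviation": worst_dev, "max_idempotence_change": worst_idem}


# ---------------------------------------------------------------------------
# bootstrap F


def _gaussian_designs(rng, n: int):
    levels = rng.integers(0, 3, size=n).astype(float)
    age = rng.normal(64, 10, size=n)
    center = (rng.random(n) < 0.65).astype(float)
    sex = (rng.random(n) < 0.45).astype(float)
    smoke = (rng.random(n) < 0.2).astype(float)
    x_null = np.column_stack([np.ones(n), age, center, sex, smoke])
    x_full = np.column_stack([levels, x_null])
    return x_full, x_null


def bootstrap_exactf_agreement(n_datasets: int = 50, n: int = 200,
                               n_boot: int = 10_000, seed: int = 0) -> dict:
    """Median |p_boot - p_exactF| on Gaussian null datasets (one exposure
    trend + four covariates)."""
    diffs = []
    for k in range(n_datasets):
        rng = _child(seed, k)
        x_full, x_null = _gaussian_designs(rng, n)
        y = x_null @ np.array([1.0, 0.01, 0.2, -0.1, 0.3]) + rng.standard_normal(n)
        res = ResidualBootstrapF(y, x_full, x_null).fit(n_boot=n_boot, seed=rng)
        diffs.append(abs(res.p_boot - res.p_exact_f))
    return {"median_abs_diff": float(np.median(diffs)), "n_datasets": n_datasets}


def type_i_error(n_features: int = 1000, n: int = 200, n_boot: int = 1000,
                 seed: int = 0, alpha: float = 0.05) -> dict:
    """Fraction of null features rejected at p_boot < alpha."""
    rng = _child(seed, 0)
    x_full, x_null = _gaussian_designs(rng, n)
    rejections = 0
    for k in range(n_features):
        y = x_null @ np.array([1.0, 0.01, 0.2, -0.1, 0.3]) \
            + _child(seed, k + 1).standard_normal(n)
        res = ResidualBootstrapF(y, x_full, x_null).fit(
            n_boot=n_boot, seed=_child(seed, 100_000 + k)
        )
        rejections += res.p_boot < alpha
    return {"rejection_fraction": rejections / n_features, "n_features": n_features}


# ---------------------------------------------------------------------------
# positive FDR


def pfdr_calibration(m: int = 10_000, pi0: float = 0.9, n_rep: int = 200,
                     effect: float = 3.0, q_threshold: float = 0.1,
                     seed: int = 0) -> dict:
    """pi0 recovery and realized false-discovery proportion at the q-gate
    on a two-group mixture of p-values (nulls uniform, alternatives from a
    shifted normal test statistic)."""
    n_alt = int(round(m * (1 - pi0)))
    pi0_hats, fdps = [], []
    for k in range(n_rep):
        rng = _child(seed, k)
        p_null = rng.random(m - n_alt)
        p_alt = stats.norm.sf(rng.standard_normal(n_alt) + effect)
        p = np.concatenate([p_null, p_alt])
        is_null = np.concatenate([np.ones(m - n_alt, bool), np.zeros(n_alt, bool)])
        res = qvalues(p)
        pi0_hats.append(res.pi0_hat)
        called = res.q < q_threshold
        fdps.append(is_null[called].sum() / max(called.sum(), 1))
    return {
        "mean_pi0_hat": float(np.mean(pi0_hats)),
        "mean_fdp": float(np.mean(fdps)),
        "true_pi0": pi0,
        "n_rep": n_rep,
    }


# ---------------------------------------------------------------------------
# survival


def _survival_dataset(rng, n: int, log_hr: float, censor_frac: float):
    age = rng.normal(64, 10, size=n)
    sex = (rng.random(n) < 0.45).astype(float)
    stage = rng.choice([1.0, 2.0, 3.0, 4.0], size=n, p=[0.2, 0.35, 0.3, 0.15])
    adjusters = np.column_stack([age, sex, stage])
    z = rng.standard_normal(n)
    rate = 2.5e-4 * np.exp(log_hr * z + 0.3 * (stage - 1) - 0.005 * (age - 64))
    t_event = rng.exponential(1.0 / rate)
    if censor_frac > 0:
        c_rate = 2.5e-4 * np.exp(0.3) * censor_frac / (1 - censor_frac)
        t_cens = rng.exponential(1.0 / c_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    return t, event, adjusters, z


def perm_lrt_chi2_agreement(n_rep: int = 100, n: int = 500, n_perm: int = 1000,
                            seed: int = 0) -> dict:
    """Null feature: median |p_perm - p_chi2(1)| and a KS uniformity check
    on the permutation p-values across replicates."""
    diffs, pperms = [], []
    for k in range(n_rep):
        rng = _child(seed, k)
        t, event, adjusters, z = _survival_dataset(rng, n, 0.0, 0.4)
        res = PermutationCoxLRT(t, event, adjusters, z).fit(n_perm=n_perm, seed=rng)
        diffs.append(abs(res.p_perm - res.p_chi2))
        pperms.append(res.p_perm)
    ks_p = float(stats.kstest(pperms, "uniform").pvalue)
    return {
        "median_abs_diff": float(np.median(diffs)),
        "ks_uniform_p": ks_p,
        "n_rep": n_rep,
    }


def cox_recovery(n_rep: int = 100, n: int = 1000, true_hr: float = 1.5,
                 censor_frac: float = 0.3, seed: int = 0,
                 hr_window: tuple = (1.35, 1.67)) -> dict:
    """Fraction of replicates whose estimated HR per SD falls in the stated
    window around the planted value, plus null CI coverage of HR = 1."""
    log_hr = float(np.log(true_hr))
    in_window = 0
    hrs = []
    for k in range(n_rep):
        rng = _child(seed, k)
        t, event, adjusters, z = _survival_dataset(rng, n, log_hr, censor_frac)
        fit = fit_cox(t, event, np.column_stack([adjusters, z]))
        hr = float(np.exp(fit.params[-1]))
        hrs.append(hr)
        in_window += hr_window[0] <= hr <= hr_window[1]
    covered = 0
    for k in range(n_rep):
        rng = _child(seed, 10_000 + k)
        t, event, adjusters, z = _survival_dataset(rng, n, 0.0, censor_frac)
        fit = fit_cox(t, event, np.column_stack([adjusters, z]))
        lo, hi = np.exp(fit.conf_int()[-1])
        covered += lo <= 1.0 <= hi
    return {
        "frac_in_window": in_window / n_rep,
        "mean_hr": float(np.mean(hrs)),
        "null_ci_coverage": covered / n_rep,
        "n_rep": n_rep,
    }


# ---------------------------------------------------------------------------
# end to end


@dataclass
class EndToEndOutcome:
    n_planted: int
    n_recovered: int
    n_significant: int
    pi0_hat: float

    @property
    def recovery_fraction(self) -> float:
        return self.n_recovered / self.n_planted if self.n_planted else float("nan")


def end_to_end_recovery(seed: int = 0, n_subjects: int = 555, n_mirna: int = 800,
                        beta: float = -0.2, frac_planted: float = 0.10,
                        n_boot: int = 1000) -> EndToEndOutcome:
    """Simulate a rectal cohort with planted exposure effects, run the
    preprocess + association + q-value chain, and measure how much of the
    planted set survives the q < 0.1 gate."""
    cfg = SimulationConfig(
        n_subjects=n_subjects, n_mirna=n_mirna, n_mrna=10,
        frac_planted_exposure=frac_planted, beta_exposure=beta,
        site="rectal", seed=seed,
    )
    cohort = simulate_cohort(cfg)
    normed, _ = normalize_75th(cohort.mirna_normal)
    kept, _ = filter_detectable(normed)
    log2 = log2_transform(kept)
    levels = categorize_cohort(cohort.exposures, cohort.subjects, "ltc_wine")
    res = AssociationScreen.from_records(
        log2, cohort.subjects, levels, exposure_variable="ltc_wine"
    ).fit(n_boot=n_boot, seed=seed)
    res.add_qvalues()
    sig = set(res.significant(0.1)["feature_id"])
    planted = set(cohort.planted_exposure_features)
    pi0_hat = estimate_pi0(res.frame["p_boot"].to_numpy())
    return EndToEndOutcome(
        n_planted=len(planted),
        n_recovered=len(planted & sig),
        n_significant=len(sig),
        pi0_hat=pi0_hat,
    )


def all_null_empty_fraction(n_rep: int = 20, seed: int = 0, n_subjects: int = 555,
                            n_mirna: int = 800, n_boot: int = 1000) -> dict:
    """Fraction of all-null cohorts whose q < 0.1 significant set is empty."""
    empty = 0
    sizes = []
    for k in range(n_rep):
        out = end_to_end_recovery(
            seed=int(_child(seed, k).integers(2**31)),
            n_subjects=n_subjects, n_mirna=n_mirna,
            beta=0.0, frac_planted=0.0, n_boot=n_boot,
        )
        sizes.append(out.n_significant)
        empty += out.n_significant == 0
    return {"frac_empty": empty / n_rep, "set_sizes": sizes, "n_rep": n_rep}
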