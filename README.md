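# mircohort

Statistical pipeline for cohort studies relating **long-term alcohol intake
to miRNA expression in colorectal tissue**, miRNA expression to **all-cause
mortality**, and mortality-associated miRNAs to **genome-wide mRNA
expression** — with a synthetic cohort generator so the whole chain is
testable without access to cohort data.

It is aimed at biostatisticians and molecular-epidemiology analysts who need
the specific combination of methods this design calls for:

* **75th-percentile scaling** of array total-gene signal: sample *s* is
  multiplied by `median_s'(q75(s')) / q75(s)`, equalizing all 75th
  percentiles exactly; plus a ≥ 20%-of-samples detectability filter and
  log2(x+1) transform.
* **Ordinal exposure coding** of eight alcohol variables
  ({LT, LTC} × {total, beer, wine, liquor}) into none/moderate/high with
  sex-specific g/day cutoffs (male 20, female 10).
* **Residual-bootstrap F tests**: per feature, OLS of log2 expression on
  the exposure trend adjusted for age, center, sex and smoking;
  `p = (1 + #{F_b ≥ F_obs}) / (B + 1)` with F_b computed on outcomes
  rebuilt from resampled null-model residuals (B = 10,000).
* **Storey positive-FDR q-values** (cubic-smoothed π̂₀, strict q < 0.1
  gate).
* **Permutation-LRT Cox models** of mortality: hazard ratios per IQR of
  expression adjusted for age, sex, center and AJCC stage;
  `p = (1 + #{LRT_perm ≥ LRT_obs}) / (P + 1)` over permutations of the
  feature column (P = 10,000), powered by a fast vectorised Efron–Newton
  partial-likelihood solver.
* **miRNA–mRNA integration**: the same bootstrap machinery with the miRNA
  as regressor, gated at q < 0.05 and screened on tumor/normal fold change
  (FC ≥ 1.50 or ≤ 0.67).

The API follows the model/results idiom: build a model object
(`ResidualBootstrapF`, `PermutationCoxLRT`, `AssociationScreen`, …), call
`.fit()`, and get a results object with estimates, uncertainties and a
`summary()`.

## Worked example

```python
from mircohort import (SimulationConfig, simulate_cohort, normalize_75th,
                       filter_detectable, log2_transform, categorize_cohort,
                       AssociationScreen, survival_screen)

cfg = SimulationConfig(n_subjects=555, n_mirna=400, n_mrna=50,
                       site="rectal", seed=12)
cohort = simulate_cohort(cfg)                      # subjects, exposures, matrices

normed, factors = normalize_75th(cohort.mirna_normal)
kept, excluded = filter_detectable(normed, min_frac=0.20)
log2 = log2_transform(kept)
print(f"{kept.n_features} of {cohort.mirna_normal.n_features} miRNAs pass the "
      f"20% detectability filter (reference q75 = {factors.reference:.1f})")

levels = categorize_cohort(cohort.exposures, cohort.subjects, "ltc_wine")
res = AssociationScreen.from_records(log2, cohort.subjects, levels,
                                     exposure_variable="ltc_wine") \
        .fit(n_boot=1000, seed=12).add_qvalues()
sig = res.significant(q_threshold=0.1)
print(f"{len(sig)} miRNAs associated with LTC wine at q < 0.1")
print(res.summary(top=5))

surv = survival_screen(log2, cohort.subjects, sig["feature_id"].tolist(),
                       n_perm=1000, seed=12)
print(surv.summary(top=3))
```

prints

```
368 of 400 miRNAs pass the 20% detectability filter (reference q75 = 904.3)
39 miRNAs associated with LTC wine at q < 0.1
Association screen (368 features, B=1000, exposure=ltc_wine)
feature_id    beta  beta_std  f_stat  df_num  df_den   p_boot       q  n_used
  mir-0393 -0.1889   -0.1784   9.884       1     547 0.000999 0.01723     553
  mir-0010  -0.221   -0.2133   13.91       1     540 0.000999 0.01723     546
  mir-0324   -0.23   -0.2278   16.39       1     543 0.000999 0.01723     549
  mir-0079 -0.2241   -0.2178   15.38       1     543 0.000999 0.01723     549
  mir-0327 -0.2187   -0.2187   15.36       1     544 0.000999 0.01723     550
Survival screen (39 features, P=1000)
feature_id   iqr  hr_per_iqr  ci_low  ci_high  lrt_stat   p_perm  n_events  n_used
  mir-0117 1.294       1.325   1.138    1.542     13.07 0.003996       277     552
  mir-0131 1.398       1.213   1.031    1.428     5.399  0.01798       275     553
  mir-0040 1.325       1.184   1.018    1.377     4.803  0.02697       275     549
```

Reading it: the cohort was generated with a planted *downward* trend in
expression across wine-consumption levels on 10% of miRNAs, and the screen
recovers them — negative standardized slopes around −0.2 per level,
bootstrap p at the 1/(B+1) floor, q-values far below the 0.1 gate. The
survival screen then reports hazard ratios per interquartile range of
expression with Wald CIs and permutation p-values; the planted mortality
miRNAs surface with HRs in the 1.2–1.3 range.

A `mircohort` CLI wraps the same stages (`simulate`, `preprocess`,
`associate`, `qvalue`, `survive`, `integrate`, `pipeline run`); `pipeline
run --config config.yaml` executes the full chain and writes per-stage TSVs
plus a JSON manifest that makes reruns byte-identical under a fixed seed.

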