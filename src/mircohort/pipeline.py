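"""End-to-end orchestration: preprocess -> association -> pFDR gate ->
survival -> miRNA-mRNA integration, with a JSON reproducibility manifest.

Stage order and wiring follow the analysis narrative: exposure screens are
run separately for colon and rectal cases and for the two outcomes
(normal-mucosa expression and the paired tumor-minus-normal difference);
the q-gated miRNAs from the normal-tissue screens feed the mortality stage
(colon and rectal combined); miRNAs with permutation p below the mortality
gate feed the mRNA integration stage.  Every stage draws its seed from a
child stream of the master seed, so a rerun with the same configuration and
seed reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .association import AssociationScreen
from .datatypes import ExpressionMatrix, Scale, ValidationError, subjects_to_frame
from .integration import mirna_mrna_screen
from .preprocess import (
    categorize_cohort,
    filter_detectable,
    log2_transform,
    normalize_75th,
    paired_difference,
)
from .qvalue import apply_gate
from .simulate import SimulationConfig, simulate_cohort
from .survival import survival_screen

DEFAULT_EXPOSURES = ("ltc_wine",)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Either point the four ``*_path`` fields at TSV inputs or set
    ``simulate`` to generate a synthetic cohort in-process.
    """

    outdir: str = "pipeline_out"
    mirna_normal_path: str | None = None
    mirna_tumor_path: str | None = None
    mrna_normal_path: str | None = None
    mrna_tumor_path: str | None = None
    subjects_path: str | None = None
    exposures_path: str | None = None
    simulate: SimulationConfig | None = None
    n_boot: int = 10_000
    n_perm: int = 10_000
    q_mirna: float = 0.1
    q_mrna: float = 0.05
    mortality_p: float = 0.05
    fc_high: float = 1.50
    fc_low: float = 0.67
    min_detect_frac: float = 0.20
    log2_offset: float = 1.0
    exposure_variables: tuple = DEFAULT_EXPOSURES
    sites: tuple = ("colon", "rectal")
    outcomes: tuple = ("normal", "difference")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 1 or self.n_perm < 1:
            raise ValidationError("n_boot and n_perm must be >= 1")
        for name in ("q_mirna", "q_mrna", "mortality_p", "fc_high", "fc_low"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulate", None)
        cfg = cls(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in raw.items()})
        if sim is not None:
            cfg.simulate = SimulationConfig(**sim)
        return cfg

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = dataclasses.asdict(self.simulate)
        return d


@dataclass
class PipelineResult:
    association: dict
    significant: dict
    survival: pd.DataFrame | None
    mortality_features: list[str]
    integration: dict
    manifest: dict


def _stage_seed(master: int, name: str) -> int:
    # stable small-int seed per stage name
    h = np.random.SeedSequence(
        entropy=master, spawn_key=(sum(ord(c) for c in name) % 1000,)
    )
    return int(h.generate_state(1)[0] % (2**31))


def _preprocess_matrix(x: ExpressionMatrix, cfg: PipelineConfig):
    normed, factors = normalize_75th(x)
    kept, excluded = filter_detectable(normed, cfg.min_detect_frac)
    return log2_transform(kept, cfg.log2_offset), factors, excluded


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.to_jsonable(), "stages": {}}
    try:
        from importlib.metadata import version

        manifest["versions"] = {"mircohort": version("mircohort"),
                                "numpy": np.__version__, "pandas": pd.__version__}
    except Exception:
        manifest["versions"] = {"numpy": np.__version__, "pandas": pd.__version__}

    # ---- load or simulate inputs -----------------------------------------
    if cfg.simulate is not None:
        cohort = simulate_cohort(cfg.simulate)
        subjects, exposures = cohort.subjects, cohort.exposures
        mirna_normal_raw, mirna_tumor_raw = cohort.mirna_normal, cohort.mirna_tumor
        mrna_normal_raw, mrna_tumor_raw = cohort.mrna_normal, cohort.mrna_tumor
        cohort.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False,
                            float_format="%.6g")
    else:
        if not (cfg.mirna_normal_path and cfg.subjects_path and cfg.exposures_path):
            raise ValidationError(
                "need mirna_normal_path, subjects_path and exposures_path "
                "(or a simulate block)"
            )
        subjects = mio.read_subjects(cfg.subjects_path)
        exposures = mio.read_exposures(cfg.exposures_path)
        mirna_normal_raw = mio.read_expression(cfg.mirna_normal_path, "normal", "mirna")
        mirna_tumor_raw = (mio.read_expression(cfg.mirna_tumor_path, "tumor", "mirna")
                           if cfg.mirna_tumor_path else None)
        mrna_normal_raw = (mio.read_expression(cfg.mrna_normal_path, "normal", "mrna")
                           if cfg.mrna_normal_path else None)
        mrna_tumor_raw = (mio.read_expression(cfg.mrna_tumor_path, "tumor", "mrna")
                          if cfg.mrna_tumor_path else None)
    subjects_df = subjects_to_frame(subjects)

    # ---- preprocessing ----------------------------------------------------
    def stage(name, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    normal_log2, normal_factors, excl_normal = stage(
        "preprocess_normal", _preprocess_matrix, mirna_normal_raw, cfg
    )
    manifest["stages"]["preprocess_normal"] = {
        "n_features_in": mirna_normal_raw.n_features,
        "n_features_kept": normal_log2.n_features,
        "n_excluded": len(excl_normal),
        "reference_q75": normal_factors.reference,
    }
    pd.Series(normal_factors.per_sample, name="factor").rename_axis("sample_id") \
        .to_csv(outdir / "scaling_factors_normal.tsv", sep="\t", float_format="%.6g")

    diff_log2 = None
    if mirna_tumor_raw is not None:
        tumor_log2, _, excl_tumor = stage(
            "preprocess_tumor", _preprocess_matrix, mirna_tumor_raw, cfg
        )
        diff_log2 = stage("paired_difference", paired_difference, tumor_log2, normal_log2)
        manifest["stages"]["preprocess_tumor"] = {
            "n_features_kept": tumor_log2.n_features,
            "n_excluded": len(excl_tumor),
            "n_paired_features": diff_log2.n_features,
            "n_paired_subjects": diff_log2.n_samples,
        }

    # ---- association screens ---------------------------------------------
    association: dict = {}
    significant: dict = {}
    all_sig_normal: list[str] = []
    site_by_id = subjects_df["site"]
    for variable in cfg.exposure_variables:
        levels = categorize_cohort(exposures, subjects, variable)
        for site in cfg.sites:
            site_subjects = [s for s in subjects if s.site.value == site]
            if not site_subjects:
                continue
            for outcome in cfg.outcomes:
                expr = normal_log2 if outcome == "normal" else diff_log2
                if expr is None:
                    continue
                key = f"{variable}_{site}_{outcome}"
                seed = _stage_seed(cfg.seed, "assoc_" + key)
                res = stage(
                    "assoc_" + key,
                    lambda: AssociationScreen.from_records(
                        expr, site_subjects, levels, exposure_variable=variable
                    ).fit(n_boot=cfg.n_boot, seed=seed),
                )
                res.add_qvalues()
                association[key] = res
                sig = apply_gate(res.frame, cfg.q_mirna)
                significant[key] = sig
                mio.write_results(res.frame, outdir / f"assoc_{key}.tsv", allow_empty=True)
                manifest["stages"]["assoc_" + key] = {
                    "seed": seed, "n_features": len(res.frame),
                    "n_skipped": len(res.skipped), "n_significant": len(sig),
                }
                if outcome == "normal":
                    all_sig_normal.extend(sig["feature_id"].tolist())

    # ---- survival on the q-gated set (sites combined) ---------------------
    surv_frame = None
    mortality_features: list[str] = []
    sig_features = sorted(set(all_sig_normal))
    if sig_features:
        seed = _stage_seed(cfg.seed, "survival")
        surv = stage(
            "survival",
            lambda: survival_screen(normal_log2, subjects, sig_features,
                                    n_perm=cfg.n_perm, seed=seed),
        )
        surv_frame = surv.frame
        mortality_features = surv.significant(cfg.mortality_p)["feature_id"].tolist()
        mio.write_results(surv_frame, outdir / "survival.tsv", allow_empty=True)
        manifest["stages"]["survival"] = {
            "seed": seed, "n_features_in": len(sig_features),
            "n_tested": len(surv_frame), "n_skipped": len(surv.skipped),
            "n_mortality_significant": len(mortality_features),
        }

    # ---- miRNA-mRNA integration -------------------------------------------
    integration: dict = {}
    if mortality_features and mrna_normal_raw is not None:
        mrna_normed, _ = normalize_75th(mrna_normal_raw)
        mrna_kept, _ = filter_detectable(mrna_normed, 0.5)
        mrna_log2 = log2_transform(mrna_kept, cfg.log2_offset)
        mrna_tumor_normed = (normalize_75th(mrna_tumor_raw)[0]
                             if mrna_tumor_raw is not None else None)
        for fid in mortality_features:
            seed = _stage_seed(cfg.seed, "integration_" + fid)
            res = stage(
                "integration_" + fid,
                lambda: mirna_mrna_screen(
                    normal_log2, mrna_log2, fid, subjects_df,
                    mrna_tumor=mrna_tumor_normed, mrna_normal_unlogged=mrna_kept,
                    n_boot=cfg.n_boot, seed=seed, q_threshold=cfg.q_mrna,
                    fc_high=cfg.fc_high, fc_low=cfg.fc_low,
                ),
            )
            integration[fid] = res
            mio.write_results(res.frame, outdir / f"mrna_{fid}.tsv", allow_empty=True)
            manifest["stages"]["integration_" + fid] = {
                "seed": seed, "n_genes": len(res.frame),
                "n_significant": len(res.significant()),
                "n_pathway_input": len(res.pathway_input()),
                "n_inverse": res.count_inverse(),
            }

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(
        association=association, significant=significant, survival=surv_frame,
        mortality_features=mortality_features, integration=integration,
        manifest=manifest,
    )
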