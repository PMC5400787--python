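"""miRNA-mRNA integration: association screen plus fold-change filter.

Mortality-associated miRNAs are tested against genome-wide mRNA expression
in normal mucosa with the same covariate-adjusted residual-bootstrap F test
used for the exposure screens, gated at q < 0.05.  Candidates are then
filtered on the tumor/normal fold change of the mRNA: only genes with
FC >= 1.50 or FC <= 0.67 (both boundaries inclusive) are kept for pathway
interpretation.  A result's direction is "inverse" when the slope of mRNA
on miRNA is negative — the canonical repressive miRNA::mRNA relationship.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import ResidualBootstrapF, build_design
from .datatypes import ExpressionMatrix, Scale, ValidationError
from .qvalue import apply_gate, qvalues

FC_HIGH_DEFAULT = 1.50
FC_LOW_DEFAULT = 0.67


def fold_change(tumor: ExpressionMatrix, normal: ExpressionMatrix, mrna_id: str,
                method: str = "ratio_of_means") -> float:
    """Tumor/normal expression ratio for one gene on the unlogged scale.

    ``ratio_of_means`` (default) divides the mean paired-subject tumor
    expression by the mean normal expression; ``mean_of_ratios`` averages
    the per-subject ratios instead.
    """
    if tumor.scale == Scale.LOG2 or normal.scale == Scale.LOG2:
        raise ValidationError("fold_change expects unlogged (raw/normalized) matrices")
    shared = [s for s in tumor.sample_ids if s in set(normal.sample_ids)]
    if not shared:
        raise ValidationError("no paired subjects between tumor and normal matrices")
    t = pd.Series(tumor.feature(mrna_id), index=tumor.sample_ids)[shared]
    n = pd.Series(normal.feature(mrna_id), index=normal.sample_ids)[shared]
    ok = ~(t.isna() | n.isna())
    if not ok.any():
        raise ValidationError(f"no complete tumor/normal pairs for {mrna_id!r}")
    t, n = t[ok], n[ok]
    if method == "ratio_of_means":
        if n.mean() == 0:
            raise ValidationError(f"zero mean normal expression for {mrna_id!r}")
        return float(t.mean() / n.mean())
    if method == "mean_of_ratios":
        if (n == 0).any():
            raise ValidationError(f"zero normal expression value for {mrna_id!r}")
        return float((t / n).mean())
    raise ValueError(f"unknown fold-change method {method!r}")


def passes_fc_screen(fc: float, fc_high: float = FC_HIGH_DEFAULT,
                     fc_low: float = FC_LOW_DEFAULT) -> bool:
    """Inclusive at both printed cutoffs: FC >= 1.50 or FC <= 0.67."""
    return fc >= fc_high or fc <= fc_low


@dataclass
class MirnaMrnaScreenResults:
    """Per-gene associations with one miRNA, plus fold-change annotation."""

    frame: pd.DataFrame
    mirna_id: str
    n_boot: int
    q_threshold: float
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def significant(self) -> pd.DataFrame:
        return apply_gate(self.frame, self.q_threshold)

    def pathway_input(self) -> pd.DataFrame:
        """Significant genes that also pass the fold-change screen."""
        sig = self.significant()
        return sig[sig["passes_fc"]].copy()

    def count_inverse(self) -> int:
        """Significant, FC-passing genes whose slope on the miRNA is negative."""
        keep = self.pathway_input()
        return int((keep["direction"] == "inverse").sum())

    def summary(self) -> str:
        sig = self.significant()
        return (
            f"miRNA-mRNA screen for {self.mirna_id}: {len(self.frame)} genes tested, "
            f"{len(sig)} with q < {self.q_threshold}, "
            f"{len(self.pathway_input())} passing the fold-change screen, "
            f"{self.count_inverse()} inverse"
        )


def mirna_mrna_screen(mirna_expr: ExpressionMatrix, mrna_expr: ExpressionMatrix,
                      mirna_id: str, subjects_df: pd.DataFrame, *,
                      mrna_tumor: ExpressionMatrix | None = None,
                      mrna_normal_unlogged: ExpressionMatrix | None = None,
                      n_boot: int = 10_000, seed: int = 0,
                      q_threshold: float = 0.05,
                      fc_high: float = FC_HIGH_DEFAULT,
                      fc_low: float = FC_LOW_DEFAULT,
                      min_overlap: int = 10) -> MirnaMrnaScreenResults:
    """Test one miRNA against every mRNA in normal mucosa.

    Per gene: linear model of mRNA log2 expression on the miRNA's log2
    expression with the usual covariate adjustment (age, center, sex,
    smoking) and a residual-bootstrap F p-value; q-values across all genes;
    fold change annotated when unlogged tumor/normal mRNA matrices are
    supplied.

    Requires at least ``min_overlap`` subjects shared between the miRNA and
    mRNA matrices.
    """
    if mirna_expr.scale != Scale.LOG2 or mrna_expr.scale != Scale.LOG2:
        raise ValidationError("mirna_mrna_screen expects log2-scale matrices")
    if mirna_id not in set(mirna_expr.feature_ids):
        raise ValidationError(f"miRNA {mirna_id!r} not present in the miRNA matrix")
    shared = sorted(
        set(mirna_expr.sample_ids) & set(mrna_expr.sample_ids) & set(subjects_df.index)
    )
    if len(shared) < min_overlap:
        raise ValidationError(
            f"only {len(shared)} overlapping subjects; need >= {min_overlap}"
        )
    # covariate-only design on the shared subjects; the tested regressor is
    # the miRNA expression rather than an exposure level
    dummy_levels = {s: 0 for s in shared}
    ids, _, _, x_null, null_names, _ = build_design(subjects_df, dummy_levels)
    mirna_vals = pd.Series(mirna_expr.feature(mirna_id), index=mirna_expr.sample_ids)
    mirna_vec = mirna_vals[ids].to_numpy(dtype=float)
    mrna_df = mrna_expr.to_frame()[ids]

    fc_cache: dict[str, float] = {}
    rows, skipped = [], []
    for k, gene in enumerate(mrna_expr.feature_ids):
        y_all = mrna_df.loc[gene].to_numpy(dtype=float)
        mask = ~(np.isnan(y_all) | np.isnan(mirna_vec))
        if mask.sum() < min_overlap:
            skipped.append((gene, f"only {int(mask.sum())} complete pairs"))
            continue
        x_full = np.column_stack([mirna_vec[mask], x_null[mask]])
        sub_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(k,))
        )
        try:
            res = ResidualBootstrapF(
                y_all[mask], x_full, x_null[mask],
                [mirna_id] + null_names,
            ).fit(n_boot=n_boot, seed=sub_rng)
        except ValidationError as exc:
            skipped.append((gene, str(exc)))
            continue
        fc = np.nan
        if mrna_tumor is not None and mrna_normal_unlogged is not None:
            try:
                fc = fold_change(mrna_tumor, mrna_normal_unlogged, gene)
            except (ValidationError, KeyError):
                fc = np.nan
        beta = float(res.params[0])
        rows.append({
            "mirna_id": mirna_id, "mrna_id": gene, "beta": beta,
            "p_boot": res.p_boot, "q": np.nan, "fold_change": fc,
            "passes_fc": bool(passes_fc_screen(fc, fc_high, fc_low))
            if not np.isnan(fc) else False,
            "direction": "inverse" if beta < 0 else "positive",
        })
    frame = pd.DataFrame(
        rows, columns=["mirna_id", "mrna_id", "beta", "p_boot", "q",
                       "fold_change", "passes_fc", "direction"],
    )
    if len(frame):
        frame["q"] = qvalues(frame["p_boot"].to_numpy()).q
    return MirnaMrnaScreenResults(
        frame=frame, mirna_id=mirna_id, n_boot=n_boot,
        q_threshold=q_threshold, skipped=skipped,
    )


def count_inverse(results: pd.DataFrame, q_threshold: float = 0.05) -> int:
    """Significant, fold-change-passing rows with a negative miRNA slope."""
    if len(results) == 0:
        return 0
    sig = apply_gate(results, q_threshold)
    return int(((sig["direction"] == "inverse") & sig["passes_fc"]).sum())
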