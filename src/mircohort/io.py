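"""Readers and writers for the pipeline's tab-delimited formats.

One dialect everywhere: UTF-8, tab delimiter, "." decimal separator, empty
string for missing.  Floats are serialised with 6 significant digits and all
result tables round-trip through their matching reader up to that formatting.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    Assay,
    Center,
    ExposureProfile,
    ExpressionMatrix,
    FormatError,
    Scale,
    Sex,
    Site,
    SubjectRecord,
    Tissue,
    ValidationError,
    BEVERAGES,
    TIMEPOINTS,
)

_FLOAT_FMT = "%.6g"

# Fixed column orders for the three result tables.
ASSOCIATION_COLUMNS = [
    "feature_id", "beta", "beta_std", "f_stat", "df_num", "df_den",
    "p_boot", "q", "n_used",
]
SURVIVAL_COLUMNS = [
    "feature_id", "iqr", "hr_per_iqr", "ci_low", "ci_high",
    "lrt_stat", "p_perm", "n_events", "n_used",
]
MRNA_COLUMNS = [
    "mirna_id", "mrna_id", "beta", "p_boot", "q", "fold_change",
    "passes_fc", "direction",
]


def read_expression(path, tissue: Tissue | str, assay: Assay | str,
                    scale: Scale | str = Scale.RAW) -> ExpressionMatrix:
    """Read a features x samples TSV: first column feature ids, header samples.

    Empty cells become NaN (missing).  Row and column order is preserved.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise FormatError(f"{path}: empty expression file")
    header = text.splitlines()[0].split("\t")[1:]
    dupes = pd.Index(header)[pd.Index(header).duplicated()].unique().tolist()
    if dupes:
        raise FormatError(f"{path}: duplicate sample id(s): {', '.join(dupes)}")
    df = pd.read_csv(_io.StringIO(text), sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected >=2 tab-separated columns")
    feature_ids = df.iloc[:, 0].astype(str).tolist()
    sample_ids = [str(c) for c in df.columns[1:]]
    try:
        values = df.iloc[:, 1:].apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric expression cell ({exc})") from None
    return ExpressionMatrix(feature_ids, sample_ids, values,
                            tissue=Tissue(tissue), assay=Assay(assay), scale=Scale(scale))


def write_expression(x: ExpressionMatrix, path) -> None:
    df = x.to_frame()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, na_rep="")


_SUBJECT_COLUMNS = [
    "subject_id", "age_dx", "sex", "center", "smoking_current", "site",
    "ajcc_stage", "survival_time", "event",
]


def _parse_bool(raw: str, field: str, subject: str) -> bool:
    if raw in ("0", "1"):
        return raw == "1"
    if raw.lower() in ("true", "false"):
        return raw.lower() == "true"
    raise FormatError(
        f"subject {subject!r}: field {field!r} must be 0/1 or true/false, got {raw!r}"
    )


def _parse_enum(raw: str, enum_cls, field: str, subject: str):
    try:
        return enum_cls(raw)
    except ValueError:
        accepted = ", ".join(e.value for e in enum_cls)
        raise FormatError(
            f"subject {subject!r}: field {field!r} value {raw!r} not recognized; "
            f"accepted values: {accepted}"
        ) from None


def read_subjects(path) -> list[SubjectRecord]:
    """Read one-row-per-subject clinical TSV into typed records."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _SUBJECT_COLUMNS if c not in df.columns and c not in ("survival_time", "event")]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    records: list[SubjectRecord] = []
    for _, row in df.iterrows():
        sid = row["subject_id"]
        surv = row.get("survival_time", "")
        ev = row.get("event", "")
        try:
            rec = SubjectRecord(
                subject_id=sid,
                age_dx=float(row["age_dx"]),
                sex=_parse_enum(row["sex"], Sex, "sex", sid),
                center=_parse_enum(row["center"], Center, "center", sid),
                smoking_current=_parse_bool(row["smoking_current"], "smoking_current", sid),
                site=_parse_enum(row["site"], Site, "site", sid),
                ajcc_stage=int(row["ajcc_stage"]),
                survival_time=float(surv) if surv != "" else None,
                event=_parse_bool(ev, "event", sid) if ev != "" else None,
            )
        except (ValueError, TypeError) as exc:
            if isinstance(exc, (FormatError, ValidationError)):
                raise
            raise FormatError(f"subject {sid!r}: {exc}") from None
        records.append(rec)
    ids = [r.subject_id for r in records]
    dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
    if dupes:
        raise FormatError(f"{path}: duplicate subject id(s): {', '.join(dupes)}")
    return records


def write_subjects(subjects: Sequence[SubjectRecord], path) -> None:
    from .datatypes import subjects_to_frame

    df = subjects_to_frame(subjects).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, na_rep="")


def _exposure_columns() -> list[str]:
    cols = [f"{b}_{tp}_gday" for b in BEVERAGES for tp in TIMEPOINTS]
    return ["subject_id", *cols, "drinks_per_month_longterm", "any_fh_alcohol_referent"]


def read_exposures(path) -> list[ExposureProfile]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = _exposure_columns()
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing exposure column(s): {', '.join(missing)}")
    profiles = []
    for _, row in df.iterrows():
        sid = row["subject_id"]
        gpd = {}
        for b in BEVERAGES:
            for tp in TIMEPOINTS:
                raw = row[f"{b}_{tp}_gday"]
                gpd[(b, tp)] = float(raw) if raw != "" else float("nan")
        profiles.append(
            ExposureProfile(
                subject_id=sid,
                grams_per_day=gpd,
                drinks_per_month_longterm=float(row["drinks_per_month_longterm"]),
                any_fh_alcohol_referent=_parse_bool(
                    row["any_fh_alcohol_referent"], "any_fh_alcohol_referent", sid
                ),
            )
        )
    return profiles


def write_exposures(profiles: Sequence[ExposureProfile], path) -> None:
    rows = []
    for p in profiles:
        row = {"subject_id": p.subject_id}
        for b in BEVERAGES:
            for tp in TIMEPOINTS:
                row[f"{b}_{tp}_gday"] = p.gday(b, tp)
        row["drinks_per_month_longterm"] = p.drinks_per_month_longterm
        row["any_fh_alcohol_referent"] = int(p.any_fh_alcohol_referent)
        rows.append(row)
    # full repr precision: the total = beer+wine+liquor identity must
    # survive the round trip exactly, which 6-digit rounding would break
    pd.DataFrame(rows, columns=_exposure_columns()).to_csv(
        path, sep="\t", index=False, na_rep=""
    )


def _result_columns(df: pd.DataFrame) -> list[str]:
    for cols in (ASSOCIATION_COLUMNS, SURVIVAL_COLUMNS, MRNA_COLUMNS):
        if set(cols).issubset(df.columns):
            return cols
    raise FormatError(
        "result table does not match any known schema; columns: "
        + ", ".join(map(str, df.columns))
    )


def write_results(results: pd.DataFrame, path, allow_empty: bool = False) -> None:
    """Write an association / survival / mRNA result table as TSV.

    Column order is fixed per schema; floats use 6 significant digits so that
    ``read_results(write_results(x)) == x`` up to that formatting.
    """
    if len(results) == 0 and not allow_empty:
        raise ValidationError("refusing to write empty result table (set allow_empty=True)")
    cols = _result_columns(results) if len(results.columns) else list(results.columns)
    results.loc[:, cols].to_csv(path, sep="\t", index=False,
                                float_format=_FLOAT_FMT, na_rep="")


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _result_columns(df)
    return df
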