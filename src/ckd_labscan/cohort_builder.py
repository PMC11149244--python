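"""Turn a raw laboratory-record table into one index assessment per patient.

Pipeline: record-level filtering (outpatient, study window, adults,
parseable values) -> index creatinine selection (chronologically first)
-> symmetric ±window urinary pairing -> diabetes flagging -> staging.

"12 months" is implemented as 365 actual days, not calendar-month
arithmetic. Records missing sex or birth year are excluded and counted
(eGFR would be incomputable), never imputed.

Input CSV dialect (gzip-transparent via pandas):
``patient_id,sex,birth_year,test_type,value,unit,collection_date,specialty,setting,region``
with ISO-8601 dates and dipstick values as tokens from the accepted set.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Literal, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import kidney_markers as km
from . import staging

__all__ = [
    "TEST_TYPES",
    "RECORD_COLUMNS",
    "PipelineConfig",
    "NoEligibleRecordsError",
    "MalformedRecordError",
    "FlowCounts",
    "read_records",
    "filter_records",
    "select_index_creatinine",
    "pair_urinary",
    "diabetes_flag",
    "build_assessments",
]

TEST_TYPES = ("creatinine", "acr", "pcr", "dipstick", "albumin_conc", "glucose", "hba1c")

RECORD_COLUMNS = [
    "patient_id",
    "sex",
    "birth_year",
    "test_type",
    "value",
    "unit",
    "collection_date",
    "specialty",
    "setting",
    "region",
]

_URINARY_TYPES = ("acr", "pcr", "dipstick")
_MODALITY_OF_TYPE = {"acr": "acr_quantitative", "pcr": "pcr_quantitative", "dipstick": "dipstick"}
# Pairing tie-break preference among urinary modalities.
_MODALITY_RANK = {"acr": 0, "pcr": 1, "dipstick": 2}


class NoEligibleRecordsError(RuntimeError):
    """All input records were excluded by the inclusion filters."""


class MalformedRecordError(ValueError):
    """A structurally broken row (e.g. unparseable date) that aborts the run."""


class PipelineConfig(BaseModel):
    """All knobs of the record-to-assessment pipeline, defaulted to the
    study design: June 2018 – May 2021 window, adult outpatients, 365-day
    symmetric pairing and diabetes look-up windows."""

    study_window_start: date = date(2018, 6, 1)
    study_window_end: date = date(2021, 5, 31)
    pairing_window_days: int = Field(365, ge=0)
    pairing_direction: Literal["both", "after", "before"] = "both"
    diabetes_window_days: int = Field(365, ge=0)
    hba1c_threshold: float = 6.5  # strict >
    glucose_threshold: float = 200.0  # strict >, mg/dL
    min_age: int = 18
    require_chronicity: bool = False
    min_stratum_n: int = 50

    @model_validator(mode="after")
    def _check_window(self) -> "PipelineConfig":
        if self.study_window_end < self.study_window_start:
            raise ValueError("study_window_end precedes study_window_start")
        return self

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)


@dataclass
class FlowCounts:
    """Record/patient accounting of the inclusion-exclusion flow.

    Every input record is counted exactly once: kept, or excluded under the
    first matching reason in the order inpatient -> window -> age ->
    unparseable (``telescopes`` asserts this).
    """

    n_records_in: int = 0
    n_excluded_inpatient: int = 0
    n_excluded_window: int = 0
    n_excluded_age: int = 0
    n_excluded_unparseable: int = 0
    n_records_kept: int = 0
    n_albumin_conc_unusable: int = 0  # kept but unusable for pairing
    n_patients: int = 0
    n_patients_no_creatinine: int = 0
    n_paired: int = 0
    n_unpaired: int = 0

    def telescopes(self) -> bool:
        records_ok = self.n_records_in == (
            self.n_excluded_inpatient
            + self.n_excluded_window
            + self.n_excluded_age
            + self.n_excluded_unparseable
            + self.n_records_kept
        )
        patients_ok = self.n_patients == self.n_paired + self.n_unpaired
        return records_ok and patients_ok

    def to_json(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Ingestion and filtering
# ---------------------------------------------------------------------------


def read_records(path: Union[str, Path]) -> pd.DataFrame:
    """Read a lab-record CSV, parsing dates strictly.

    Raises :class:`MalformedRecordError` naming the first offending row
    (1-based, excluding the header) if a collection date does not parse.
    """
    df = pd.read_csv(path, dtype={"value": str, "patient_id": str}, keep_default_na=False)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedRecordError(f"input CSV is missing columns: {missing}")
    parsed = pd.to_datetime(df["collection_date"], format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise MalformedRecordError(
            f"unparseable collection_date {df['collection_date'].iloc[row - 1]!r} at data row {row}"
        )
    df = df.copy()
    df["collection_date"] = parsed
    df["record_id"] = np.arange(len(df))
    return df


def _parse_values(df: pd.DataFrame) -> Tuple[pd.Series, pd.Series, pd.Series]:
    """Per-record parsed numeric value / dipstick category / validity mask.

    Numeric tests are unit-normalized (creatinine to mg/dL, ratios to mg/g).
    """
    value_num = pd.Series(np.nan, index=df.index, dtype=float)
    dip_cat = pd.Series(pd.NA, index=df.index, dtype=object)
    ok = pd.Series(True, index=df.index)

    ttype = df["test_type"]
    unit = df["unit"].astype(str)
    raw = pd.to_numeric(df["value"], errors="coerce")

    numeric_mask = ttype.isin(["creatinine", "acr", "pcr", "albumin_conc", "glucose", "hba1c"])
    ok &= ~(numeric_mask & (raw.isna() | (raw <= 0)))

    value_num[numeric_mask] = raw[numeric_mask]
    for tt, conv, default_unit in (
        ("creatinine", km.creatinine_to_mgdl, "mg/dl"),
        ("acr", km.ratio_to_mgg, "mg/g"),
        ("pcr", km.ratio_to_mgg, "mg/g"),
    ):
        m = (ttype == tt) & ok
        if m.any():
            units_here = unit[m].str.strip().str.lower().replace("", default_unit)
            for u in units_here.unique():
                sel = m & (units_here.reindex(df.index) == u)
                try:
                    factor = conv(1.0, u)
                except km.InputDomainError:
                    ok &= ~sel
                    continue
                value_num[sel] = raw[sel] * factor

    dip_mask = ttype == "dipstick"
    if dip_mask.any():
        for token in df.loc[dip_mask, "value"].unique():
            sel = dip_mask & (df["value"] == token)
            try:
                dip_cat[sel] = km.parse_dipstick_token(token)
            except km.DipstickParseError:
                ok &= ~sel

    ok &= ttype.isin(TEST_TYPES)
    return value_num, dip_cat, ok


def filter_records(
    records: pd.DataFrame, config: Optional[PipelineConfig] = None
) -> Tuple[pd.DataFrame, FlowCounts]:
    """Apply the inclusion filters and account for every dropped record.

    Drops inpatient records, records outside the study window, records from
    patients under ``min_age`` at the test date, and unparseable rows
    (bad value, bad unit, missing sex/birth year). Deterministic given input
    order; raises :class:`NoEligibleRecordsError` if nothing survives.
    """
    config = config or PipelineConfig()
    if len(records) == 0:
        raise NoEligibleRecordsError("input record table is empty")
    df = records.copy()
    if "record_id" not in df.columns:
        df["record_id"] = np.arange(len(df))
    if not pd.api.types.is_datetime64_any_dtype(df["collection_date"]):
        df["collection_date"] = pd.to_datetime(df["collection_date"], format="%Y-%m-%d")

    counts = FlowCounts(n_records_in=len(df))
    alive = pd.Series(True, index=df.index)

    inpatient = df["setting"].astype(str).str.strip().str.lower() != "outpatient"
    counts.n_excluded_inpatient = int((alive & inpatient).sum())
    alive &= ~inpatient

    start = pd.Timestamp(config.study_window_start)
    end = pd.Timestamp(config.study_window_end)
    outside = (df["collection_date"] < start) | (df["collection_date"] > end)
    counts.n_excluded_window = int((alive & outside).sum())
    alive &= ~outside

    birth_year = pd.to_numeric(df["birth_year"], errors="coerce")
    sex = df["sex"].astype(str).str.strip().str.lower()
    demo_ok = birth_year.notna() & sex.isin(["female", "male"])
    age = df["collection_date"].dt.year - birth_year
    underage = demo_ok & (age < config.min_age)
    counts.n_excluded_age = int((alive & underage).sum())
    alive &= ~underage

    value_num, dip_cat, parse_ok = _parse_values(df)
    bad = ~(parse_ok & demo_ok)
    counts.n_excluded_unparseable = int((alive & bad).sum())
    alive &= ~bad

    kept = df[alive].copy()
    kept["sex"] = sex[alive]
    kept["birth_year"] = birth_year[alive].astype(int)
    kept["age_at_test"] = age[alive].astype(int)
    kept["value_num"] = value_num[alive]
    kept["dipstick_category"] = dip_cat[alive]
    counts.n_records_kept = len(kept)
    counts.n_albumin_conc_unusable = int((kept["test_type"] == "albumin_conc").sum())
    if counts.n_records_kept == 0:
        raise NoEligibleRecordsError("no eligible records after filtering")
    return kept, counts


# ---------------------------------------------------------------------------
# Per-patient operations (scalar contracts; the bulk path is vectorized)
# ---------------------------------------------------------------------------


def select_index_creatinine(
    patient_records: pd.DataFrame,
) -> Tuple[pd.Series, pd.DataFrame]:
    """Index creatinine for one patient: chronologically first, ties on the
    same date broken by smallest record id. Returns (index row, later
    creatinine records kept for follow-up analysis)."""
    creats = patient_records[patient_records["test_type"] == "creatinine"]
    if len(creats) == 0:
        raise NoEligibleRecordsError("patient has no creatinine record")
    creats = creats.sort_values(["collection_date", "record_id"], kind="mergesort")
    index_row = creats.iloc[0]
    later = creats[creats["collection_date"] > index_row["collection_date"]]
    return index_row, later


def _window_mask(delta_days: pd.Series, window_days: int, direction: str) -> pd.Series:
    if direction == "both":
        return delta_days.abs() <= window_days
    if direction == "after":
        return (delta_days >= 0) & (delta_days <= window_days)
    return (delta_days <= 0) & (delta_days >= -window_days)


def pair_urinary(
    index_row: pd.Series,
    urinary_records: pd.DataFrame,
    window_days: int = 365,
    direction: str = "both",
) -> Optional[Tuple[km.PacrValue, pd.Timestamp, str]]:
    """Pair the index creatinine with its best urinary record, if any.

    Among in-window candidates: smallest \\|Δdate\\| wins; ties prefer the later
    record, then quantitative ACR > PCR > dipstick, then smallest record id.
    Returns (pACR, urinary date, urinary requesting specialty) or None.
    """
    cand = urinary_records[urinary_records["test_type"].isin(_URINARY_TYPES)].copy()
    if len(cand) == 0:
        return None
    delta = (cand["collection_date"] - index_row["collection_date"]).dt.days
    cand = cand[_window_mask(delta, window_days, direction)]
    if len(cand) == 0:
        return None
    delta = (cand["collection_date"] - index_row["collection_date"]).dt.days
    cand = cand.assign(
        _absd=delta.abs(),
        _negd=-delta,
        _rank=cand["test_type"].map(_MODALITY_RANK),
    ).sort_values(["_absd", "_negd", "_rank", "record_id"], kind="mergesort")
    best = cand.iloc[0]
    if best["test_type"] == "dipstick":
        u = km.UrinaryResult("dipstick", dipstick_category=best["dipstick_category"])
    else:
        u = km.UrinaryResult(
            _MODALITY_OF_TYPE[best["test_type"]], quantitative_value=float(best["value_num"])
        )
    return km.pacr_from_any(u), best["collection_date"], str(best["specialty"])


def diabetes_flag(
    index_row: pd.Series,
    glycemic_records: pd.DataFrame,
    window_days: int = 365,
) -> bool:
    """True iff any HbA1c > 6.5 % or glucose > 200 mg/dL (strict) lies within
    ``window_days`` of the index date."""
    g = glycemic_records[glycemic_records["test_type"].isin(["glucose", "hba1c"])]
    if len(g) == 0:
        return False
    delta = (g["collection_date"] - index_row["collection_date"]).dt.days
    g = g[delta.abs() <= window_days]
    high = ((g["test_type"] == "hba1c") & (g["value_num"] > 6.5)) | (
        (g["test_type"] == "glucose") & (g["value_num"] > 200.0)
    )
    return bool(high.any())


# ---------------------------------------------------------------------------
# Bulk assessment construction (vectorized)
# ---------------------------------------------------------------------------

ASSESSMENT_COLUMNS = [
    "patient_id",
    "index_date",
    "index_scr",
    "egfr",
    "g_stage",
    "paired",
    "pacr",
    "pacr_date",
    "pacr_modality",
    "pacr_specialty",
    "a_category",
    "ckd_status",
    "diabetes",
    "specialty",
    "age_at_index",
    "sex",
]


def _index_table(kept: pd.DataFrame) -> pd.DataFrame:
    creat = kept[kept["test_type"] == "creatinine"]
    creat = creat.sort_values(["patient_id", "collection_date", "record_id"], kind="mergesort")
    return creat.groupby("patient_id", as_index=False, sort=True).first()

def _pair_all(
    kept: pd.DataFrame, index: pd.DataFrame, config: PipelineConfig
) -> pd.DataFrame:
    urinary = kept[kept["test_type"].isin(_URINARY_TYPES)].copy()
    if len(urinary) == 0:
        return pd.DataFrame(
            columns=["patient_id", "pacr", "pacr_date", "pacr_modality", "pacr_specialty"]
        )
    urinary = urinary.merge(
        index[["patient_id", "collection_date"]].rename(columns={"collection_date": "index_date"}),
        on="patient_id",
        how="inner",
    )
    delta = (urinary["collection_date"] - urinary["index_date"]).dt.days
    urinary = urinary[_window_mask(delta, config.pairing_window_days, config.pairing_direction)]
    if len(urinary) == 0:
        return pd.DataFrame(
            columns=["patient_id", "pacr", "pacr_date", "pacr_modality", "pacr_specialty"]
        )
    delta = (urinary["collection_date"] - urinary["index_date"]).dt.days
    urinary = urinary.assign(
        _absd=delta.abs(), _negd=-delta, _rank=urinary["test_type"].map(_MODALITY_RANK)
    )
    urinary = urinary.sort_values(
        ["patient_id", "_absd", "_negd", "_rank", "record_id"], kind="mergesort"
    )
    best = urinary.groupby("patient_id", as_index=False, sort=True).first()

    pacr = np.full(len(best), np.nan)
    is_acr = (best["test_type"] == "acr").to_numpy()
    is_pcr = (best["test_type"] == "pcr").to_numpy()
    is_dip = (best["test_type"] == "dipstick").to_numpy()
    vals = best["value_num"].to_numpy(dtype=float)
    pacr[is_acr] = vals[is_acr]
    if is_pcr.any():
        pacr[is_pcr] = km.pacr_from_pcr_values(vals[is_pcr])
    if is_dip.any():
        dip_pacr = {
            c: km.pacr_from_dipstick(c).value for c in km.DIPSTICK_CATEGORIES
        }
        pacr[is_dip] = best.loc[is_dip, "dipstick_category"].map(dip_pacr).to_numpy(dtype=float)

    return pd.DataFrame(
        {
            "patient_id": best["patient_id"],
            "pacr": pacr,
            "pacr_date": best["collection_date"],
            "pacr_modality": best["test_type"].map(_MODALITY_OF_TYPE),
            "pacr_specialty": best["specialty"],
        }
    )


def _diabetes_all(kept: pd.DataFrame, index: pd.DataFrame, config: PipelineConfig) -> pd.Series:
    g = kept[kept["test_type"].isin(["glucose", "hba1c"])]
    if len(g) == 0:
        return pd.Series(False, index=index["patient_id"])
    g = g.merge(
        index[["patient_id", "collection_date"]].rename(columns={"collection_date": "index_date"}),
        on="patient_id",
        how="inner",
    )
    delta = (g["collection_date"] - g["index_date"]).dt.days
    g = g[delta.abs() <= config.diabetes_window_days]
    high = ((g["test_type"] == "hba1c") & (g["value_num"] > config.hba1c_threshold)) | (
        (g["test_type"] == "glucose") & (g["value_num"] > config.glucose_threshold)
    )
    flagged = g.loc[high, "patient_id"].unique()
    return pd.Series(index["patient_id"].isin(flagged).to_numpy(), index=index["patient_id"])


def build_assessments(
    records: pd.DataFrame, config: Optional[PipelineConfig] = None
) -> Tuple[pd.DataFrame, FlowCounts]:
    """One index assessment per patient from a raw (or pre-filtered) table.

    Returns the assessment table (``ASSESSMENT_COLUMNS``) and the flow
    accounting. Patients whose kept records contain no creatinine are
    excluded and counted in ``n_patients_no_creatinine``.
    """
    config = config or PipelineConfig()
    if "value_num" in records.columns:  # already filtered
        kept = records
        counts = FlowCounts(n_records_in=len(records), n_records_kept=len(records))
    else:
        kept, counts = filter_records(records, config)

    index = _index_table(kept)
    n_all_patients = kept["patient_id"].nunique()
    counts.n_patients = len(index)
    counts.n_patients_no_creatinine = int(n_all_patients - len(index))
    if len(index) == 0:
        raise NoEligibleRecordsError("no patient has an eligible creatinine record")

    female = (index["sex"] == "female").to_numpy()
    egfr = km.egfr_values(
        index["value_num"].to_numpy(dtype=float),
        index["age_at_test"].to_numpy(dtype=float),
        female,
    )
    gs = staging.g_stage_values(egfr)

    pairs = _pair_all(kept, index, config)
    out = index[
        ["patient_id", "collection_date", "value_num", "specialty", "age_at_test", "sex"]
    ].rename(
        columns={
            "collection_date": "index_date",
            "value_num": "index_scr",
            "age_at_test": "age_at_index",
        }
    )
    out["egfr"] = egfr
    out["g_stage"] = gs
    out = out.merge(pairs, on="patient_id", how="left")
    out["paired"] = out["pacr"].notna()

    a_cat = pd.Series(pd.NA, index=out.index, dtype=object)
    paired_mask = out["paired"].to_numpy()
    if paired_mask.any():
        a_cat[paired_mask] = staging.a_category_values(out.loc[paired_mask, "pacr"].to_numpy())
    out["a_category"] = a_cat

    low_gfr = out["g_stage"].isin(["G3a", "G3b", "G4", "G5"]).to_numpy()
    status = np.where(
        low_gfr,
        "ckd",
        np.where(
            ~paired_mask,
            "indeterminate",
            np.where(a_cat.isin(["A2", "A3"]).to_numpy(), "ckd", "no_ckd"),
        ),
    )
    if config.require_chronicity:
        status = np.where(status == "ckd", "indeterminate", status)
    out["ckd_status"] = status

    diab = _diabetes_all(kept, index, config)
    out["diabetes"] = out["patient_id"].map(diab).fillna(False).astype(bool)

    out = out[ASSESSMENT_COLUMNS].sort_values("patient_id", kind="mergesort").reset_index(drop=True)
    counts.n_paired = int(out["paired"].sum())
    counts.n_unpaired = int((~out["paired"]).sum())
    assert counts.telescopes(), "flow counts do not telescope"
    return out, counts
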