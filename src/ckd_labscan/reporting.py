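"""Output surfaces: the KDIGO cross-tabulation summary, per-stage pairing
and albuminuria fractions, specialty shares, KM summaries, and the pipeline
composition that ties everything together.

Denominator conventions (fixed once):
  * CKD fraction and stage shares — the paired (classifiable) population;
  * pairing fractions — all indexed patients per stage;
  * A3 fractions — paired patients per stage;
  * specialty shares — all index creatinine records.
Percentages are reported to one decimal; JSON floats are rounded to six
significant digits with sorted keys, so identical inputs produce identical
files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Dict, Optional, Union

import numpy as np
import pandas as pd

from . import cohort_builder as cb
from . import followup_km as fkm
from .staging import A_CATEGORIES, G_STAGES

__all__ = [
    "StageSummary",
    "summarize",
    "run_pipeline",
    "dump_json",
    "validate_summary",
]

SIX_MONTHS_DAYS = 183


@dataclass
class StageSummary:
    """Every headline quantity of the analysis as a named field."""

    n_indexed: int
    n_paired: int
    n_unpaired: int
    unpaired_fraction: float
    ckd_fraction_among_paired: float
    stage_share_among_ckd: Dict[str, float]
    pairing_fraction_by_stage: Dict[str, float]
    a3_fraction_by_stage: Dict[str, float]
    crosstab: Dict[str, Dict[str, int]]  # G stage -> {A1, A2, A3, missing} counts
    risk_counts: Dict[str, int]
    mean_age_by_ckd_status: Dict[str, float]
    diabetes_prev_by_ckd_status: Dict[str, float]
    specialty_share_overall: Dict[str, float]
    specialty_share_by_stage: Dict[str, Dict[str, float]]
    km_ci_6mo_by_stage: Dict[str, float] = field(default_factory=dict)
    km_se_6mo_by_stage: Dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> Dict[str, Any]:
        return asdict(self)


def _share(series: pd.Series, denominator: int) -> Dict[str, float]:
    counts = series.value_counts()
    return {str(k): counts.get(k, 0) / denominator for k in counts.index}


def summarize(
    assessments: pd.DataFrame,
    km_curves: Optional[Dict[str, fkm.KMCurve]] = None,
) -> StageSummary:
    """Deterministic aggregation of the assessment table (and optional KM
    curves) into one summary object. Permutation-invariant in row order."""
    if len(assessments) == 0:
        raise ValueError("no assessments to summarize")
    n = len(assessments)
    paired = assessments[assessments["paired"]]
    ckd = assessments[assessments["ckd_status"] == "ckd"]
    ckd_paired = paired[paired["ckd_status"] == "ckd"]

    stage_share_ckd = {
        s: float((ckd["g_stage"] == s).sum()) / len(ckd) if len(ckd) else None
        for s in G_STAGES
    }
    pairing_by_stage, a3_by_stage = {}, {}
    crosstab: Dict[str, Dict[str, int]] = {}
    for s in G_STAGES:
        sub = assessments[assessments["g_stage"] == s]
        subp = sub[sub["paired"]]
        pairing_by_stage[s] = len(subp) / len(sub) if len(sub) else None
        a3_by_stage[s] = (
            float((subp["a_category"] == "A3").sum()) / len(subp) if len(subp) else None
        )
        crosstab[s] = {a: int((subp["a_category"] == a).sum()) for a in A_CATEGORIES}
        crosstab[s]["missing"] = int(len(sub) - len(subp))

    from .staging import kdigo_risk

    risk_counts = {r: 0 for r in ("low", "moderately_increased", "high", "very_high")}
    for s in G_STAGES:
        for a in A_CATEGORIES:
            risk_counts[kdigo_risk(s, a)] += crosstab[s][a]

    mean_age = {}
    diab_prev = {}
    for status in ("ckd", "no_ckd", "indeterminate"):
        sub = assessments[assessments["ckd_status"] == status]
        mean_age[status] = float(sub["age_at_index"].mean()) if len(sub) else None
        diab_prev[status] = float(sub["diabetes"].mean()) if len(sub) else None

    summary = StageSummary(
        n_indexed=n,
        n_paired=int(len(paired)),
        n_unpaired=int(n - len(paired)),
        unpaired_fraction=(n - len(paired)) / n,
        ckd_fraction_among_paired=len(ckd_paired) / len(paired) if len(paired) else None,
        stage_share_among_ckd=stage_share_ckd,
        pairing_fraction_by_stage=pairing_by_stage,
        a3_fraction_by_stage=a3_by_stage,
        crosstab=crosstab,
        risk_counts=risk_counts,
        mean_age_by_ckd_status=mean_age,
        diabetes_prev_by_ckd_status=diab_prev,
        specialty_share_overall=_share(assessments["specialty"], n),
        specialty_share_by_stage={
            s: _share(
                assessments.loc[assessments["g_stage"] == s, "specialty"],
                max(int((assessments["g_stage"] == s).sum()), 1),
            )
            for s in G_STAGES
        },
    )
    if km_curves:
        for s, curve in km_curves.items():
            summary.km_ci_6mo_by_stage[s] = curve.ci_at(SIX_MONTHS_DAYS)
            summary.km_se_6mo_by_stage[s] = curve.se_at(SIX_MONTHS_DAYS)
    return summary


# ---------------------------------------------------------------------------
# Stable JSON output and schema validation
# ---------------------------------------------------------------------------


def _round_sig(x: float, sig: int = 6) -> Optional[float]:
    if not np.isfinite(x):
        return None  # JSON-safe null for empty-stratum placeholders
    if x == 0:
        return x
    return float(f"{x:.{sig}g}")


def _round_floats(obj: Any) -> Any:
    if isinstance(obj, float):
        return _round_sig(obj)
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v) for v in obj]
    return obj


def dump_json(payload: Dict[str, Any], path: Union[str, Path]) -> None:
    """Write JSON with sorted keys and floats at 6 significant digits."""
    with open(path, "w") as fh:
        json.dump(_round_floats(payload), fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")


def _load_schema() -> Dict[str, Any]:
    with resources.files("ckd_labscan.schemas").joinpath("summary.schema.json").open() as fh:
        return json.load(fh)


def validate_summary(payload: Dict[str, Any]) -> None:
    """Check a summary dict against the shipped schema (required keys and
    primitive types only — intentionally minimal)."""
    schema = _load_schema()
    for key, expected in schema["properties"].items():
        if key in schema.get("required", []) and key not in payload:
            raise ValueError(f"summary is missing required key {key!r}")
        if key not in payload:
            continue
        kind = expected["type"]
        value = payload[key]
        ok = {
            "integer": lambda v: isinstance(v, (int, np.integer)) and not isinstance(v, bool),
            "number": lambda v: isinstance(v, (int, float, np.floating)) and not isinstance(v, bool),
            "object": lambda v: isinstance(v, dict),
        }[kind](value)
        if not ok:
            raise ValueError(f"summary key {key!r} has wrong type: expected {kind}")


# ---------------------------------------------------------------------------
# Pipeline composition
# ---------------------------------------------------------------------------


def run_pipeline(
    records_csv: Union[str, Path],
    config: Optional[cb.PipelineConfig] = None,
    outdir: Optional[Union[str, Path]] = None,
):
    """filter -> build_assessments -> follow-up KM -> summarize.

    Returns (assessments, flow_counts, summary, km_curves); when ``outdir``
    is given also writes assessments.csv, flow.json, summary.json and one
    km_<stage>.csv per non-empty stratum.
    """
    config = config or cb.PipelineConfig()
    records = cb.read_records(records_csv)
    kept, counts = cb.filter_records(records, config)
    assessments, counts2 = cb.build_assessments(kept, config)
    # merge record-level counts (filter) with patient-level counts (builder)
    counts2.n_records_in = counts.n_records_in
    counts2.n_excluded_inpatient = counts.n_excluded_inpatient
    counts2.n_excluded_window = counts.n_excluded_window
    counts2.n_excluded_age = counts.n_excluded_age
    counts2.n_excluded_unparseable = counts.n_excluded_unparseable
    counts2.n_albumin_conc_unusable = counts.n_albumin_conc_unusable
    assert counts2.telescopes()

    observations = fkm.make_followup_observations(assessments, kept, config.study_window_end)
    km_curves = fkm.stratify_km(observations, config.min_stratum_n)
    summary = summarize(assessments, km_curves)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        out_assess = assessments.copy()
        for col in ("index_date", "pacr_date"):
            out_assess[col] = pd.to_datetime(out_assess[col]).dt.strftime("%Y-%m-%d")
        out_assess.to_csv(outdir / "assessments.csv", index=False)
        counts2.to_json(outdir / "flow.json")
        payload = summary.to_dict()
        validate_summary(payload)
        dump_json(payload, outdir / "summary.json")
        for s, curve in km_curves.items():
            curve.to_frame().to_csv(outdir / f"km_{s}.csv", index=False)
    return assessments, counts2, summary, km_curves
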