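"""Stage-stratified cumulative incidence of a repeat creatinine measurement.

The estimand is one minus the Kaplan-Meier survival function of the time
from the index creatinine to the first strictly later creatinine, with
administrative censoring at the study close date. At tied event/censor
times events precede censorings (standard product-limit convention).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .staging import G_STAGES

__all__ = [
    "KMCurve",
    "make_followup_observations",
    "condition_on_retest",
    "km_cumulative_incidence",
    "stratify_km",
]

logger = logging.getLogger(__name__)


@dataclass
class KMCurve:
    """A product-limit cumulative-incidence curve for one stratum.

    ``times`` are the sorted distinct event times; ``cumulative_incidence``
    is right-continuous, starts at CI(0) = 0 and is non-decreasing.
    ``se`` is the Greenwood standard error of the survival estimate.
    """

    stratum: str
    times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    cumulative_incidence: np.ndarray
    se: np.ndarray
    n_total: int
    n_events_total: int
    flagged_small: bool = False

    def ci_at(self, t: float) -> float:
        """Cumulative incidence at time ``t`` (step function, right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.cumulative_incidence[idx])

    def se_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.se[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
                "cumulative_incidence": self.cumulative_incidence,
                "se": self.se,
            }
        )


def make_followup_observations(
    assessments: pd.DataFrame,
    creatinine_records: pd.DataFrame,
    study_end,
) -> pd.DataFrame:
    """Time-to-first-repeat-creatinine observations, one row per patient.

    A repeat must be strictly later than the index date (same-day repeats are
    not events). Patients without a later creatinine are censored at
    ``study_end``. Columns: patient_id, g_stage, time (days), event.
    """
    study_end = pd.Timestamp(study_end)
    creat = creatinine_records[creatinine_records["test_type"] == "creatinine"]
    merged = creat.merge(
        assessments[["patient_id", "index_date"]], on="patient_id", how="inner"
    )
    later = merged[merged["collection_date"] > merged["index_date"]]
    first_later = (
        later.groupby("patient_id", sort=False)["collection_date"].min().rename("event_date")
    )
    obs = assessments[["patient_id", "g_stage", "index_date"]].merge(
        first_later, on="patient_id", how="left"
    )
    has_event = obs["event_date"].notna()
    time = np.where(
        has_event,
        (obs["event_date"] - obs["index_date"]).dt.days,
        (study_end - obs["index_date"]).dt.days,
    ).astype(float)
    assert (time >= 0).all(), "negative follow-up time"
    return pd.DataFrame(
        {
            "patient_id": obs["patient_id"],
            "g_stage": obs["g_stage"],
            "time": time,
            "event": has_event.to_numpy(),
        }
    )


def condition_on_retest(observations: pd.DataFrame) -> pd.DataFrame:
    """Restrict to patients with an observed repeat test (the "at least two
    tests" conditional variant some summaries use)."""
    return observations[observations["event"]].copy()


def km_cumulative_incidence(
    observations: pd.DataFrame, stratum: str = "pooled"
) -> KMCurve:
    """Product-limit estimate: CI(t) = 1 − Π_{t_i ≤ t} (1 − d_i / n_i).

    With no censoring this degenerates to the empirical CDF of event times.
    An all-censored input yields CI ≡ 0 with a warning.
    """
    if len(observations) == 0:
        raise ValueError("need at least one observation")
    time = observations["time"].to_numpy(dtype=float)
    event = observations["event"].to_numpy(dtype=bool)
    n = len(time)

    if not event.any():
        warnings.warn(f"stratum {stratum!r}: all observations censored; CI is identically 0")
        return KMCurve(
            stratum=stratum,
            times=np.array([]),
            n_at_risk=np.array([], dtype=int),
            n_events=np.array([], dtype=int),
            cumulative_incidence=np.array([]),
            se=np.array([]),
            n_total=n,
            n_events_total=0,
        )

    # distinct event times; at-risk counts use "events before censorings" at ties
    event_times = np.unique(time[event])
    d = np.array([(event & (time == t)).sum() for t in event_times]) if len(event_times) < 64 else None
    if d is None:
        # vectorized path for large inputs
        order = np.searchsorted(event_times, time[event])
        d = np.bincount(order, minlength=len(event_times))
    # n_at_risk at t: subjects with observed time >= t
    sorted_all = np.sort(time)
    at_risk = n - np.searchsorted(sorted_all, event_times, side="left")

    frac = 1.0 - d / at_risk
    surv = np.cumprod(frac)
    # Greenwood: Var(S) = S^2 * cumsum(d / (n (n - d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.cumsum(d / (at_risk * (at_risk - d).clip(min=0)))
    se = surv * np.sqrt(np.where(np.isfinite(gw), gw, 0.0))

    return KMCurve(
        stratum=stratum,
        times=event_times,
        n_at_risk=at_risk.astype(int),
        n_events=d.astype(int),
        cumulative_incidence=1.0 - surv,
        se=se,
        n_total=n,
        n_events_total=int(event.sum()),
    )


def stratify_km(
    observations: pd.DataFrame, min_stratum_n: int = 50
) -> Dict[str, KMCurve]:
    """Independent KM curve per G stage; empty strata are omitted with a log
    message, small strata are flagged."""
    curves: Dict[str, KMCurve] = {}
    for stage in G_STAGES:
        sub = observations[observations["g_stage"] == stage]
        if len(sub) == 0:
            logger.info("stratum %s empty; omitted", stage)
            continue
        curve = km_cumulative_incidence(sub, stratum=stage)
        if len(sub) < min_stratum_n:
            curve.flagged_small = True
        curves[stage] = curve
    return curves
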