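"""KDIGO classification: G stage from eGFR, A category from pACR, the CKD
flag, and the 18-cell prognosis ("risk heatmap") mapping.

Boundary conventions (declared once, used everywhere):
  G bands half-open with the lower bound included: G1 [90, ∞), G2 [60, 90),
  G3a [45, 60), G3b [30, 45), G4 [15, 30), G5 (0, 15).
  A bands: A1 (0, 30), A2 [30, 300], A3 (300, ∞) in mg/g creatinine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .kidney_markers import InputDomainError, PacrValue

__all__ = [
    "G_STAGES",
    "A_CATEGORIES",
    "RISK_LEVELS",
    "GStage",
    "ACategory",
    "KdigoCell",
    "g_stage",
    "g_stage_values",
    "a_category",
    "a_category_values",
    "ckd_flag",
    "kdigo_risk",
    "classify",
]

G_STAGES = ("G1", "G2", "G3a", "G3b", "G4", "G5")
A_CATEGORIES = ("A1", "A2", "A3")
RISK_LEVELS = ("low", "moderately_increased", "high", "very_high")

# Lower eGFR bound of each stage, descending.
_G_LOWER = ((90.0, "G1"), (60.0, "G2"), (45.0, "G3a"), (30.0, "G3b"), (15.0, "G4"), (0.0, "G5"))

# The standard KDIGO 18-cell prognosis grid.
_KDIGO_RISK = {
    ("G1", "A1"): "low",
    ("G2", "A1"): "low",
    ("G1", "A2"): "moderately_increased",
    ("G2", "A2"): "moderately_increased",
    ("G3a", "A1"): "moderately_increased",
    ("G1", "A3"): "high",
    ("G2", "A3"): "high",
    ("G3a", "A2"): "high",
    ("G3b", "A1"): "high",
    ("G3a", "A3"): "very_high",
    ("G3b", "A2"): "very_high",
    ("G3b", "A3"): "very_high",
    ("G4", "A1"): "very_high",
    ("G4", "A2"): "very_high",
    ("G4", "A3"): "very_high",
    ("G5", "A1"): "very_high",
    ("G5", "A2"): "very_high",
    ("G5", "A3"): "very_high",
}

GStage = str
ACategory = str


@dataclass(frozen=True)
class KdigoCell:
    """One cell of the KDIGO grid with its derived risk level and CKD flag."""

    g: GStage
    a: ACategory
    risk: str
    ckd: bool


def g_stage(egfr: float) -> GStage:
    """Map an eGFR (mL/min/1.73 m²) to its KDIGO G stage."""
    if not (math.isfinite(egfr) and egfr > 0):
        raise InputDomainError(f"eGFR must be finite and > 0, got {egfr}")
    for lower, label in _G_LOWER:
        if egfr >= lower:
            return label
    return "G5"  # pragma: no cover — unreachable, egfr > 0 matches the last band


def g_stage_values(egfr: np.ndarray) -> np.ndarray:
    """Vectorized ``g_stage`` (no domain checking)."""
    egfr = np.asarray(egfr, dtype=float)
    edges = [90.0, 60.0, 45.0, 30.0, 15.0]
    conds = [egfr >= e for e in edges]
    return np.select(conds, G_STAGES[:5], default="G5")


def a_category(pacr: Union[PacrValue, float]) -> ACategory:
    """Map a pACR (mg/g) to its KDIGO albuminuria category."""
    value = pacr.value if isinstance(pacr, PacrValue) else float(pacr)
    if not (math.isfinite(value) and value > 0):
        raise InputDomainError(f"pACR must be finite and > 0, got {value}")
    if value < 30.0:
        return "A1"
    if value <= 300.0:
        return "A2"
    return "A3"


def a_category_values(pacr: np.ndarray) -> np.ndarray:
    """Vectorized ``a_category`` (no domain checking)."""
    pacr = np.asarray(pacr, dtype=float)
    return np.select([pacr < 30.0, pacr <= 300.0], ["A1", "A2"], default="A3")


def ckd_flag(
    g: GStage,
    a: Optional[ACategory] = None,
    *,
    require_chronicity: bool = False,
    confirmed: bool = False,
) -> str:
    """CKD status from a single G stage and (possibly missing) A category.

    G3a–G5 is CKD regardless of albuminuria; G1/G2 is CKD iff albuminuria is
    A2/A3, no-CKD with A1, and indeterminate when the A category is missing.

    By default a single assessment suffices (no chronicity requirement),
    matching an assumption of no false positives from single measurements.
    With ``require_chronicity=True``, positives are downgraded to
    ``indeterminate`` unless ``confirmed`` marks >= 90-day persistence.
    """
    if g not in G_STAGES:
        raise InputDomainError(f"unknown G stage {g!r}")
    if a is not None and a not in A_CATEGORIES:
        raise InputDomainError(f"unknown A category {a!r}")
    if g in ("G3a", "G3b", "G4", "G5"):
        status = "ckd"
    elif a is None:
        return "indeterminate"
    else:
        status = "ckd" if a in ("A2", "A3") else "no_ckd"
    if status == "ckd" and require_chronicity and not confirmed:
        return "indeterminate"
    return status


def kdigo_risk(g: GStage, a: ACategory) -> str:
    """Risk level of one KDIGO heatmap cell."""
    try:
        return _KDIGO_RISK[(g, a)]
    except KeyError:
        raise InputDomainError(f"not a KDIGO cell: ({g!r}, {a!r})") from None


def classify(g: GStage, a: ACategory) -> KdigoCell:
    """Full cell classification: risk level plus CKD flag."""
    return KdigoCell(g=g, a=a, risk=kdigo_risk(g, a), ckd=ckd_flag(g, a) == "ckd")
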