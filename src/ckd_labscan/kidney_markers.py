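"""Pure computational core: eGFR from serum creatinine and conversion of any
urinary protein measurement into a predicted albumin-to-creatinine ratio (pACR).

Units are fixed throughout the package: serum creatinine in mg/dL, urinary
ratios (ACR, PCR, pACR) in mg/g creatinine.  Converters for the two common
alternative units (creatinine in µmol/L, ratios in mg/mmol) are provided for
input normalization.

All "log"/"exp" in the crosswalk equations are natural logarithms: the printed
equations only round-trip (exp of a sum of logs) under base e.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

__all__ = [
    "InputDomainError",
    "DipstickParseError",
    "CreatinineResult",
    "UrinaryResult",
    "PacrValue",
    "DIPSTICK_CATEGORIES",
    "parse_dipstick_token",
    "egfr_ckdepi_2021",
    "egfr_values",
    "pacr_from_pcr",
    "pacr_from_pcr_values",
    "pacr_from_dipstick",
    "pacr_from_any",
    "creatinine_to_mgdl",
    "ratio_to_mgg",
]

Sex = Literal["female", "male"]
Modality = Literal["acr_quantitative", "pcr_quantitative", "dipstick"]


class InputDomainError(ValueError):
    """Raised when a physiologically/mathematically invalid input is supplied."""


class DipstickParseError(ValueError):
    """Raised for an unrecognized semi-quantitative dipstick token."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CreatinineResult:
    """A serum creatinine result with the demographics needed for eGFR.

    Parameters
    ----------
    value : float
        Serum creatinine, mg/dL. Must be positive.
    age : int
        Age in whole years at collection. Must be >= 18 (adult cohort).
    sex : {"female", "male"}
    """

    value: float
    age: int
    sex: Sex

    def __post_init__(self) -> None:
        if not (math.isfinite(self.value) and self.value > 0):
            raise InputDomainError(f"serum creatinine must be finite and > 0, got {self.value}")
        if self.age < 18:
            raise InputDomainError(f"adult cohort requires age >= 18, got {self.age}")
        if self.sex not in ("female", "male"):
            raise InputDomainError(f"sex must be 'female' or 'male', got {self.sex!r}")


# Ordinal dipstick grades, in increasing order of proteinuria.  The ">++" bin
# absorbs every grade above "++".
DIPSTICK_CATEGORIES = ("negative", "trace", "plus", "plusplus", "above_plusplus")

_DIPSTICK_TOKEN_MAP = {
    "negative": "negative",
    "neg": "negative",
    "-": "negative",
    "trace": "trace",
    "+": "plus",
    "1+": "plus",
    "plus": "plus",
    "++": "plusplus",
    "2+": "plusplus",
    "plusplus": "plusplus",
    ">++": "above_plusplus",
    "3+": "above_plusplus",
    "4+": "above_plusplus",
    "+++": "above_plusplus",
    "++++": "above_plusplus",
    "above_plusplus": "above_plusplus",
}


def parse_dipstick_token(token: str) -> str:
    """Normalize a raw dipstick token to one of ``DIPSTICK_CATEGORIES``."""
    key = str(token).strip().lower()
    try:
        return _DIPSTICK_TOKEN_MAP[key]
    except KeyError:
        accepted = ", ".join(sorted(_DIPSTICK_TOKEN_MAP))
        raise DipstickParseError(
            f"unrecognized dipstick token {token!r}; accepted tokens: {accepted}"
        ) from None


@dataclass(frozen=True)
class UrinaryResult:
    """One urinary proteinuria result in one of three modalities.

    Exactly one of ``quantitative_value`` (mg/g creatinine, for the two
    quantitative modalities) or ``dipstick_category`` must be populated.
    """

    modality: Modality
    quantitative_value: Optional[float] = None
    dipstick_category: Optional[str] = None

    def __post_init__(self) -> None:
        if self.modality in ("acr_quantitative", "pcr_quantitative"):
            if self.quantitative_value is None or self.dipstick_category is not None:
                raise InputDomainError(
                    f"{self.modality} requires quantitative_value only"
                )
            if not (math.isfinite(self.quantitative_value) and self.quantitative_value > 0):
                raise InputDomainError(
                    f"quantitative urinary value must be finite and > 0, got {self.quantitative_value}"
                )
        elif self.modality == "dipstick":
            if self.dipstick_category is None or self.quantitative_value is not None:
                raise InputDomainError("dipstick requires dipstick_category only")
            if self.dipstick_category not in DIPSTICK_CATEGORIES:
                object.__setattr__(
                    self, "dipstick_category", parse_dipstick_token(self.dipstick_category)
                )
        else:
            raise InputDomainError(f"unknown urinary modality {self.modality!r}")


@dataclass(frozen=True)
class PacrValue:
    """A predicted albumin-to-creatinine ratio, mg/g creatinine."""

    value: float
    source_modality: Modality

    def __post_init__(self) -> None:
        if not (math.isfinite(self.value) and self.value > 0):
            raise InputDomainError(f"pACR must be finite and > 0, got {self.value}")


# ---------------------------------------------------------------------------
# eGFR: CKD-EPI 2021 race-free creatinine equation
# ---------------------------------------------------------------------------

# 2021 CKD-EPI refit (creatinine only, without race), adult population.
# Reference: Inker LA et al., N Engl J Med 2021;385:1737-1749 (eGFRcr).
_EGFR_SCALE = 142.0
_EGFR_AGE_BASE = 0.9938
_EGFR_FEMALE_FACTOR = 1.012
_EGFR_KAPPA = {"female": 0.7, "male": 0.9}
_EGFR_ALPHA = {"female": -0.241, "male": -0.302}
_EGFR_BETA = -1.200


def egfr_values(
    scr: np.ndarray, age: np.ndarray, female: np.ndarray
) -> np.ndarray:
    """Vectorized CKD-EPI 2021 eGFR (mL/min/1.73 m²).

    ``scr`` in mg/dL, ``age`` in years, ``female`` boolean mask.
    No domain checking: caller validates.
    """
    scr = np.asarray(scr, dtype=float)
    age = np.asarray(age, dtype=float)
    female = np.asarray(female, dtype=bool)
    kappa = np.where(female, _EGFR_KAPPA["female"], _EGFR_KAPPA["male"])
    alpha = np.where(female, _EGFR_ALPHA["female"], _EGFR_ALPHA["male"])
    ratio = scr / kappa
    out = (
        _EGFR_SCALE
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** _EGFR_BETA
        * _EGFR_AGE_BASE**age
    )
    return np.where(female, out * _EGFR_FEMALE_FACTOR, out)


def egfr_ckdepi_2021(scr: CreatinineResult) -> float:
    """Estimated GFR (mL/min/1.73 m²) via the 2021 race-free CKD-EPI equation.

    Strictly decreasing in creatinine at fixed age/sex, and in age at fixed
    creatinine/sex.

    Examples
    --------
    >>> round(egfr_ckdepi_2021(CreatinineResult(0.7, 50, "female")), 1)
    105.3
    """
    return float(
        egfr_values(
            np.array([scr.value]),
            np.array([scr.age]),
            np.array([scr.sex == "female"]),
        )[0]
    )


# ---------------------------------------------------------------------------
# pACR crosswalks
# ---------------------------------------------------------------------------

# PCR -> pACR crosswalk (three clamped natural-log terms with knots at
# PCR = 50 and PCR = 500 mg/g).
_PCR_INTERCEPT = 5.3920
_PCR_COEF_LOW = 0.3072  # log(min(PCR/50, 1))
_PCR_COEF_MID = 1.5793  # log(max(min(PCR/500, 1), 0.1))
_PCR_COEF_HIGH = 1.1266  # log(max(PCR/500, 1))

# Dipstick grade -> pACR crosswalk: intercept plus one indicator coefficient.
_DIPSTICK_INTERCEPT = 2.4738
_DIPSTICK_COEF = {
    "negative": 0.0,
    "trace": 0.7539,
    "plus": 1.7243,
    "plusplus": 3.3475,
    "above_plusplus": 4.6399,
}


def pacr_from_pcr_values(pcr: np.ndarray) -> np.ndarray:
    """Vectorized PCR (mg/g) -> pACR (mg/g) crosswalk. No domain checking."""
    pcr = np.asarray(pcr, dtype=float)
    return np.exp(
        _PCR_INTERCEPT
        + _PCR_COEF_LOW * np.log(np.minimum(pcr / 50.0, 1.0))
        + _PCR_COEF_MID * np.log(np.maximum(np.minimum(pcr / 500.0, 1.0), 0.1))
        + _PCR_COEF_HIGH * np.log(np.maximum(pcr / 500.0, 1.0))
    )


def pacr_from_pcr(pcr: float) -> PacrValue:
    """Convert a quantitative protein-to-creatinine ratio to predicted ACR.

    Strictly increasing and continuous on (0, ∞); at PCR = 500 all three
    clamped log terms vanish and pACR = exp(5.3920) ≈ 219.7 mg/g.
    """
    if not (math.isfinite(pcr) and pcr > 0):
        raise InputDomainError(f"PCR must be finite and > 0, got {pcr}")
    return PacrValue(float(pacr_from_pcr_values(np.array([pcr]))[0]), "pcr_quantitative")


def pacr_from_dipstick(category: str) -> PacrValue:
    """Convert a semi-quantitative dipstick grade to predicted ACR (mg/g)."""
    if category not in _DIPSTICK_COEF:
        category = parse_dipstick_token(category)
    return PacrValue(
        math.exp(_DIPSTICK_INTERCEPT + _DIPSTICK_COEF[category]), "dipstick"
    )


def pacr_from_any(u: UrinaryResult) -> PacrValue:
    """Route any urinary result to its pACR conversion.

    Quantitative ACR passes through unchanged; PCR and dipstick results go
    through their respective crosswalk equations. The source modality is
    recorded on the returned value.
    """
    if u.modality == "acr_quantitative":
        return PacrValue(float(u.quantitative_value), "acr_quantitative")
    if u.modality == "pcr_quantitative":
        return pacr_from_pcr(float(u.quantitative_value))
    return pacr_from_dipstick(u.dipstick_category)


# ---------------------------------------------------------------------------
# Unit normalization
# ---------------------------------------------------------------------------

_CREATININE_UNIT_FACTORS = {
    "mg/dl": 1.0,
    "umol/l": 1.0 / 88.42,
    "µmol/l": 1.0 / 88.42,
    "μmol/l": 1.0 / 88.42,
}

_RATIO_UNIT_FACTORS = {
    "mg/g": 1.0,
    "mg/mmol": 8.84,
}


def creatinine_to_mgdl(value: float, unit: str) -> float:
    """Normalize a serum creatinine value to mg/dL (µmol/L divided by 88.42)."""
    try:
        factor = _CREATININE_UNIT_FACTORS[unit.strip().lower()]
    except KeyError:
        raise InputDomainError(
            f"unsupported creatinine unit {unit!r}; expected mg/dL or µmol/L"
        ) from None
    return value * factor


def ratio_to_mgg(value: float, unit: str) -> float:
    """Normalize a urinary ratio (ACR/PCR) to mg/g creatinine (mg/mmol × 8.84)."""
    try:
        factor = _RATIO_UNIT_FACTORS[unit.strip().lower()]
    except KeyError:
        raise InputDomainError(
            f"unsupported ratio unit {unit!r}; expected mg/g or mg/mmol"
        ) from None
    return value * factor
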