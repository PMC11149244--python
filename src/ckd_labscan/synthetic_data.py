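"""Seeded synthetic laboratory-record generator.

Emits a flat lab-record table (the CSV dialect consumed by
:mod:`ckd_labscan.cohort_builder`) whose latent statistical structure the
pipeline is supposed to recover: a stage × CKD × albuminuria cell mixture
for the paired subpopulation, per-stage pairing odds (unpaired patients are
reconstructed at N_paired·(1−p)/p per stage), stage-dependent exponential
retest hazards with administrative truncation at study end, per-stage
requesting-specialty mixes, and CKD-dependent demographics.

The marginal stage distribution over *all* tested patients is never
configured directly; it emerges from the paired-population composition plus
the per-stage pairing odds. Likewise the overall unpaired fraction is an
emergent composite. True eGFR is drawn uniform within each stage band
(simplest choice making classification recovery exact); the retest process
is exponential per stage so Kaplan-Meier recovery has an analytic oracle.
"""

from __future__ import annotations

from datetime import date
from functools import lru_cache
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import brentq

from .kidney_markers import (
    InputDomainError,
    UrinaryResult,
    egfr_values,
    pacr_from_pcr_values,
    _EGFR_AGE_BASE,
    _EGFR_ALPHA,
    _EGFR_BETA,
    _EGFR_FEMALE_FACTOR,
    _EGFR_KAPPA,
    _EGFR_SCALE,
)
from .staging import G_STAGES

__all__ = [
    "LATENT_CELLS",
    "STAGE_BANDS",
    "SPECIALTIES",
    "GeneratorConfig",
    "invert_egfr_to_creatinine",
    "sample_urinary_for_category",
    "generate_cohort",
    "write_cohort",
]

LATENT_CELLS = ("G1_noCKD", "G2_noCKD", "G1_CKD", "G2_CKD", "G3a", "G3b", "G4", "G5")
_CELL_STAGE = {
    "G1_noCKD": "G1",
    "G2_noCKD": "G2",
    "G1_CKD": "G1",
    "G2_CKD": "G2",
    "G3a": "G3a",
    "G3b": "G3b",
    "G4": "G4",
    "G5": "G5",
}
_CELL_CKD = {c: not c.endswith("noCKD") for c in LATENT_CELLS}

# True-eGFR band per stage; G5 truncated below at 4, G1 above at 120.
STAGE_BANDS = {
    "G1": (90.0, 120.0),
    "G2": (60.0, 90.0),
    "G3a": (45.0, 60.0),
    "G3b": (30.0, 45.0),
    "G4": (15.0, 30.0),
    "G5": (4.0, 15.0),
}
_BAND_MARGIN = 1e-6

SPECIALTIES = ("internal_medicine", "cardiology", "obgyn", "endocrinology", "nephrology", "other")

_REGIONS = ("SP", "RJ", "PR", "other")
_REGION_P = (0.476, 0.226, 0.093, 0.205)


def _with_other(shares: Dict[str, float]) -> Dict[str, float]:
    out = dict(shares)
    out["other"] = 1.0 - sum(shares.values())
    return out


# G1/G2 nephrology share solved so the emergent overall nephrology share of
# index creatinine tests is 0.011 given the default stage weights.
_NEPH_G12 = 0.004271997697491632

_DEFAULT_SPECIALTY_MIX = {
    "G1": _with_other(
        {"internal_medicine": 0.172, "cardiology": 0.123, "obgyn": 0.207,
         "endocrinology": 0.0882, "nephrology": _NEPH_G12}
    ),
    "G2": _with_other(
        {"internal_medicine": 0.177, "cardiology": 0.186, "obgyn": 0.130,
         "endocrinology": 0.0882, "nephrology": _NEPH_G12}
    ),
    "G3a": _with_other(
        {"internal_medicine": 0.188, "cardiology": 0.232, "obgyn": 0.02,
         "endocrinology": 0.087, "nephrology": 0.05}
    ),
    "G3b": _with_other(
        {"internal_medicine": 0.17, "cardiology": 0.18, "obgyn": 0.01,
         "endocrinology": 0.09, "nephrology": 0.125}
    ),
    "G4": _with_other(
        {"internal_medicine": 0.149, "cardiology": 0.13, "obgyn": 0.01,
         "endocrinology": 0.09, "nephrology": 0.125}
    ),
    "G5": _with_other(
        {"internal_medicine": 0.217, "cardiology": 0.094, "obgyn": 0.005,
         "endocrinology": 0.03, "nephrology": 0.39}
    ),
}

# Paired-subpopulation latent-cell mixture: 10.8% CKD with stage shares
# (6.8, 8.3, 54.1, 22.1, 6.1, 2.6)% across G1..G5; the non-CKD remainder is
# split G1:G2 = 55:45 (an explicit calibration knob).
_DEFAULT_STAGE_MIXTURE = {
    "G1_noCKD": 0.892 * 0.55,
    "G2_noCKD": 0.892 * 0.45,
    "G1_CKD": 0.108 * 0.068,
    "G2_CKD": 0.108 * 0.083,
    "G3a": 0.108 * 0.541,
    "G3b": 0.108 * 0.221,
    "G4": 0.108 * 0.061,
    "G5": 0.108 * 0.026,
}


class GeneratorConfig(BaseModel):
    """All latent parameters of the synthetic population."""

    n_patients: int = Field(10_000, gt=0, description="number of PAIRED patients drawn")
    seed: int = 0
    study_window_start: date = date(2018, 6, 1)
    study_window_end: date = date(2021, 5, 31)
    stage_mixture: Dict[str, float] = Field(default_factory=lambda: dict(_DEFAULT_STAGE_MIXTURE))
    pairing_prob_by_stage: Dict[str, float] = Field(
        default_factory=lambda: {"G1": 0.549, "G2": 0.612, "G3a": 0.667,
                                 "G3b": 0.707, "G4": 0.702, "G5": 0.467}
    )
    a3_prob_by_stage: Dict[str, float] = Field(
        default_factory=lambda: {"G1": 0.003, "G2": 0.004, "G3a": 0.012,
                                 "G3b": 0.025, "G4": 0.073, "G5": 0.284}
    )
    urinary_modality_mix: Dict[str, float] = Field(
        default_factory=lambda: {"acr_quantitative": 0.5, "pcr_quantitative": 0.3, "dipstick": 0.2}
    )
    retest_rate_per_month_by_stage: Dict[str, float] = Field(
        default_factory=lambda: {"G1": 0.1407, "G2": 0.1407, "G3a": 0.15,
                                 "G3b": 0.1527, "G4": 0.2524, "G5": 0.40}
    )
    specialty_mix_by_stage: Dict[str, Dict[str, float]] = Field(
        default_factory=lambda: {s: dict(d) for s, d in _DEFAULT_SPECIALTY_MIX.items()}
    )
    age_mean_ckd: float = 69.0
    age_sd_ckd: float = 15.2
    age_mean_nonckd: float = 47.2
    age_sd_nonckd: float = 15.4
    age_min: int = 18
    age_max: int = 120
    diabetes_prev_ckd: float = 0.22
    diabetes_prev_nonckd: float = 0.08
    sex_female_prob: float = 0.60
    days_per_month: float = 30.4375
    max_repeats_per_patient: int = 6

    @model_validator(mode="after")
    def _validate(self) -> "GeneratorConfig":
        for name, vec in (
            ("stage_mixture", self.stage_mixture),
            ("urinary_modality_mix", self.urinary_modality_mix),
        ):
            if abs(sum(vec.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {sum(vec.values())}")
        if set(self.stage_mixture) != set(LATENT_CELLS):
            raise ValueError(f"stage_mixture must have keys {LATENT_CELLS}")
        for s, mix in self.specialty_mix_by_stage.items():
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"specialty mix for {s} must sum to 1")
        for s in G_STAGES:
            if not 0 < self.pairing_prob_by_stage[s] <= 1:
                raise ValueError("pairing probabilities must be in (0, 1]")
            if self.retest_rate_per_month_by_stage[s] <= 0:
                raise ValueError("retest hazards must be > 0")
        return self

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "GeneratorConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# eGFR inversion
# ---------------------------------------------------------------------------


def invert_egfr_to_creatinine(target_egfr: float, age: int, sex: str) -> float:
    """Serum creatinine (mg/dL) whose eGFR equals ``target_egfr``.

    Bisection (Brent) on the strictly monotone creatinine -> eGFR map;
    the returned creatinine reproduces the target to < 1e-8.
    """
    if not (1.0 < target_egfr < 200.0):
        raise InputDomainError(f"target eGFR {target_egfr} outside supported range (1, 200)")
    female = np.array([sex == "female"])
    age_arr = np.array([float(age)])

    def f(scr: float) -> float:
        return float(egfr_values(np.array([scr]), age_arr, female)[0]) - target_egfr

    lo, hi = 1e-4, 60.0
    if f(lo) < 0 or f(hi) > 0:
        raise InputDomainError(
            f"eGFR {target_egfr} not achievable for age {age}, sex {sex}"
        )
    return float(brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16))


def _invert_egfr_vectorized(target: np.ndarray, age: np.ndarray, female: np.ndarray) -> np.ndarray:
    """Closed-form inverse of the piecewise-power eGFR map (bulk path).

    Agrees with :func:`invert_egfr_to_creatinine` to < 1e-10 (tested)."""
    kappa = np.where(female, _EGFR_KAPPA["female"], _EGFR_KAPPA["male"])
    alpha = np.where(female, _EGFR_ALPHA["female"], _EGFR_ALPHA["male"])
    base = _EGFR_SCALE * _EGFR_AGE_BASE ** age * np.where(female, _EGFR_FEMALE_FACTOR, 1.0)
    ratio = target / base  # = f(scr/kappa); > 1 needs the alpha branch
    return kappa * np.where(
        ratio >= 1.0, ratio ** (1.0 / alpha), ratio ** (1.0 / _EGFR_BETA)
    )


# ---------------------------------------------------------------------------
# Category-consistent urinary sampling
# ---------------------------------------------------------------------------

# pACR sampling band per A category, kept strictly inside the thresholds.
_PACR_BANDS = {"A1": (3.0, 30.0 - 1e-4), "A2": (30.0 + 1e-4, 300.0 - 1e-4), "A3": (300.0 + 1e-4, 2000.0)}

_DIPSTICK_FOR_CAT = {
    "A1": (("negative", "trace"), (0.7, 0.3)),
    "A2": (("plus",), (1.0,)),
    "A3": (("plusplus", "above_plusplus"), (0.8, 0.2)),
}


@lru_cache(maxsize=None)
def _invert_pacr_to_pcr(pacr: float) -> float:
    """PCR whose crosswalk image equals ``pacr`` (bisection; map is strictly
    increasing from 0 to ∞)."""
    f = lambda p: float(pacr_from_pcr_values(np.array([p]))[0]) - pacr
    return float(brentq(f, 1e-6, 1e7, xtol=1e-12, rtol=8.9e-16))


@lru_cache(maxsize=None)
def _pcr_band(a_cat: str) -> Tuple[float, float]:
    lo, hi = _PACR_BANDS[a_cat]
    return _invert_pacr_to_pcr(lo), _invert_pacr_to_pcr(hi)


def sample_urinary_for_category(
    a_cat: str, modality: str, rng: np.random.Generator
) -> UrinaryResult:
    """Draw one urinary result guaranteed to convert into the given A category.

    Quantitative ACR is log-uniform within the category's mg/g band; PCR is
    log-uniform within the numerically inverted crosswalk pre-image of the
    band; dipstick grades come from the category-compatible tokens.
    """
    if modality == "dipstick":
        tokens, probs = _DIPSTICK_FOR_CAT[a_cat]
        return UrinaryResult("dipstick", dipstick_category=rng.choice(tokens, p=probs))
    lo, hi = _pcr_band(a_cat) if modality == "pcr_quantitative" else _PACR_BANDS[a_cat]
    value = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return UrinaryResult(modality, quantitative_value=value)


def _sample_urinary_bulk(
    a_cat: np.ndarray, modality: np.ndarray, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Bulk version of :func:`sample_urinary_for_category`.

    Returns (string value column, test_type column) aligned with inputs."""
    n = len(a_cat)
    value = np.empty(n, dtype=object)
    ttype = np.empty(n, dtype=object)
    for cat in ("A1", "A2", "A3"):
        for mod, tt in (("acr_quantitative", "acr"), ("pcr_quantitative", "pcr"), ("dipstick", "dipstick")):
            m = (a_cat == cat) & (modality == mod)
            k = int(m.sum())
            if k == 0:
                continue
            ttype[m] = tt
            if tt == "dipstick":
                tokens, probs = _DIPSTICK_FOR_CAT[cat]
                value[m] = rng.choice(tokens, p=probs, size=k)
            else:
                lo, hi = _pcr_band(cat) if tt == "pcr" else _PACR_BANDS[cat]
                draws = np.exp(rng.uniform(np.log(lo), np.log(hi), size=k))
                value[m] = np.char.mod("%.10g", draws)
    return value, ttype


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _truncated_normal_int(
    mean: np.ndarray, sd: np.ndarray, lo: int, hi: int, rng: np.random.Generator
) -> np.ndarray:
    """Integer ages from a normal, redrawn (not clipped) outside [lo, hi]."""
    out = np.rint(rng.normal(mean, sd)).astype(int)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = np.rint(rng.normal(mean[bad], sd[bad])).astype(int)
        bad = (out < lo) | (out > hi)
    return out


def _latent_population(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the latent patient table: paired cells by the configured mixture,
    plus per-stage unpaired patients at N_paired·(1−p)/p."""
    cells = np.array(LATENT_CELLS)
    probs = np.array([config.stage_mixture[c] for c in LATENT_CELLS])
    counts = rng.multinomial(config.n_patients, probs)
    cell = np.repeat(cells, counts)
    stage = np.array([_CELL_STAGE[c] for c in cell])
    ckd = np.array([_CELL_CKD[c] for c in cell])
    paired = np.ones(len(cell), dtype=bool)

    # A category per paired patient
    a_cat = np.empty(len(cell), dtype=object)
    a_cat[~ckd] = "A1"
    for s, cell_name in (("G1", "G1_CKD"), ("G2", "G2_CKD")):
        m = cell == cell_name
        k = int(m.sum())
        if k == 0:
            continue
        stage_mass = config.stage_mixture[s + "_noCKD"] + config.stage_mixture[cell_name]
        p_a3 = config.a3_prob_by_stage[s] * stage_mass / config.stage_mixture[cell_name]
        if p_a3 > 1:
            raise ValueError(f"a3_prob_by_stage[{s}] inconsistent with stage_mixture")
        a_cat[m] = np.where(rng.random(k) < p_a3, "A3", "A2")
    for s in ("G3a", "G3b", "G4", "G5"):
        m = cell == s
        k = int(m.sum())
        if k == 0:
            continue
        u = rng.random(k)
        p_a3 = config.a3_prob_by_stage[s]
        # remaining mass split evenly between A1 and A2
        a_cat[m] = np.where(u < p_a3, "A3", np.where(u < p_a3 + (1 - p_a3) / 2, "A1", "A2"))

    # unpaired reconstruction per stage
    add_stage, add_ckd = [], []
    for s in G_STAGES:
        n_p = int((stage == s).sum())
        p = config.pairing_prob_by_stage[s]
        n_u = int(round(n_p * (1 - p) / p))
        if n_u == 0:
            continue
        add_stage.append(np.full(n_u, s, dtype=object))
        if s in ("G1", "G2"):
            m_ckd = config.stage_mixture[s + "_CKD"]
            m_tot = m_ckd + config.stage_mixture[s + "_noCKD"]
            p_ckd = m_ckd / m_tot if m_tot > 0 else 0.0
            add_ckd.append(rng.random(n_u) < p_ckd)
        else:
            add_ckd.append(np.ones(n_u, dtype=bool))
    if add_stage:
        stage = np.concatenate([stage, np.concatenate(add_stage)])
        ckd = np.concatenate([ckd, np.concatenate(add_ckd)])
        paired = np.concatenate([paired, np.zeros(sum(len(a) for a in add_stage), dtype=bool)])
        a_cat = np.concatenate([a_cat, np.full(sum(len(a) for a in add_stage), None, dtype=object)])

    n = len(stage)
    return pd.DataFrame(
        {
            "patient_id": np.char.add("P", np.char.zfill(np.arange(n).astype(str), 8)),
            "stage": stage,
            "latent_ckd": ckd,
            "paired": paired,
            "a_category": a_cat,
        }
    )


def generate_cohort(config: GeneratorConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the lab-record table and its latent-truth sidecar.

    Fully reproducible given ``config.seed``: two runs with the same config
    produce identical tables.
    """
    rng = np.random.default_rng(config.seed)
    truth = _latent_population(config, rng)
    n = len(truth)
    stage = truth["stage"].to_numpy()
    ckd = truth["latent_ckd"].to_numpy()

    # demographics
    female = rng.random(n) < config.sex_female_prob
    mean = np.where(ckd, config.age_mean_ckd, config.age_mean_nonckd)
    sd = np.where(ckd, config.age_sd_ckd, config.age_sd_nonckd)
    age = _truncated_normal_int(mean, sd, config.age_min, config.age_max, rng)
    diabetes = rng.random(n) < np.where(ckd, config.diabetes_prev_ckd, config.diabetes_prev_nonckd)

    # true eGFR inside the stage band, away from boundaries
    lo = np.array([STAGE_BANDS[s][0] for s in stage]) + _BAND_MARGIN
    hi = np.array([STAGE_BANDS[s][1] for s in stage]) - _BAND_MARGIN
    egfr_true = rng.uniform(lo, hi)
    scr = _invert_egfr_vectorized(egfr_true, age.astype(float), female)

    # index date uniform in the study window
    start = pd.Timestamp(config.study_window_start)
    end = pd.Timestamp(config.study_window_end)
    window_days = (end - start).days
    index_off = rng.integers(0, window_days + 1, size=n)
    index_date = start + pd.to_timedelta(index_off, unit="D")

    sex_str = np.where(female, "female", "male")
    birth_year = index_date.year.to_numpy() - age
    region = rng.choice(_REGIONS, p=_REGION_P, size=n)

    def draw_specialty(stages: np.ndarray) -> np.ndarray:
        out = np.empty(len(stages), dtype=object)
        for s in G_STAGES:
            m = stages == s
            k = int(m.sum())
            if k == 0:
                continue
            mix = config.specialty_mix_by_stage[s]
            names = list(mix)
            out[m] = rng.choice(names, p=np.array([mix[x] for x in names]), size=k)
        return out

    specialty = draw_specialty(stage)

    # Patients aged exactly age_min at index would appear underage (and get
    # filtered) on any record dated in the previous calendar year; keep their
    # auxiliary records within the index year or later.
    min_offset = np.where(
        age == config.age_min, -(index_date.dayofyear.to_numpy() - 1), -365
    )

    def frame(mask, test_type, value, unit, offs, spec) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": truth["patient_id"].to_numpy()[mask],
                "sex": sex_str[mask],
                "birth_year": birth_year[mask],
                "test_type": test_type,
                "value": value,
                "unit": unit,
                "collection_date": (start + pd.to_timedelta(index_off[mask] + offs, unit="D")).strftime(
                    "%Y-%m-%d"
                ),
                "specialty": spec,
                "setting": "outpatient",
                "region": region[mask],
            }
        )

    all_mask = np.ones(n, dtype=bool)
    records = [
        frame(all_mask, "creatinine", np.char.mod("%.10g", scr), "mg/dL", 0, specialty)
    ]

    # one urinary record per paired patient, within ±365 d clipped to the window
    paired = truth["paired"].to_numpy()
    npair = int(paired.sum())
    if npair:
        mods = np.array(list(config.urinary_modality_mix))
        modality = rng.choice(
            mods, p=np.array([config.urinary_modality_mix[m] for m in mods]), size=npair
        )
        uval, uttype = _sample_urinary_bulk(
            truth["a_category"].to_numpy()[paired].astype(object), modality, rng
        )
        d_lo = np.maximum(min_offset[paired], -index_off[paired])
        d_hi = np.minimum(365, window_days - index_off[paired])
        u_off = rng.integers(d_lo, d_hi + 1)
        unit = np.where(uttype == "dipstick", "", "mg/g")
        records.append(
            frame(paired, uttype, uval, unit, u_off, draw_specialty(stage[paired]))
        )

    # glycemic records: diabetics always get one discriminating result;
    # 70% of non-diabetics get a normal result (both test types exercised)
    emit_gly = diabetes | (rng.random(n) < 0.7)
    kg = int(emit_gly.sum())
    if kg:
        is_hba1c = rng.random(kg) < 0.6
        diab_g = diabetes[emit_gly]
        val = np.where(
            is_hba1c,
            np.where(diab_g, rng.uniform(6.6, 10.0, kg), rng.uniform(4.8, 6.4, kg)),
            np.where(diab_g, rng.uniform(201.0, 350.0, kg), rng.uniform(70.0, 199.0, kg)),
        )
        g_lo = np.maximum(min_offset[emit_gly], -index_off[emit_gly])
        g_hi = np.minimum(365, window_days - index_off[emit_gly])
        g_off = rng.integers(g_lo, g_hi + 1)
        records.append(
            frame(
                emit_gly,
                np.where(is_hba1c, "hba1c", "glucose"),
                np.char.mod("%.6g", val),
                np.where(is_hba1c, "%", "mg/dL"),
                g_off,
                draw_specialty(stage[emit_gly]),
            )
        )

    # repeat creatinines: exponential inter-test gaps, truncated at study end
    daily_rate = np.array(
        [config.retest_rate_per_month_by_stage[s] for s in stage]
    ) / config.days_per_month
    gaps = rng.exponential(1.0, size=(n, config.max_repeats_per_patient)) / daily_rate[:, None]
    days = np.ceil(np.cumsum(gaps, axis=1)).astype(int)
    keep = days <= (window_days - index_off)[:, None]
    rep_idx, rep_k = np.nonzero(keep)
    if len(rep_idx):
        rep_mask_value = np.char.mod("%.10g", scr[rep_idx])
        records.append(
            pd.DataFrame(
                {
                    "patient_id": truth["patient_id"].to_numpy()[rep_idx],
                    "sex": sex_str[rep_idx],
                    "birth_year": birth_year[rep_idx],
                    "test_type": "creatinine",
                    "value": rep_mask_value,
                    "unit": "mg/dL",
                    "collection_date": (
                        start + pd.to_timedelta(index_off[rep_idx] + days[rep_idx, rep_k], unit="D")
                    ).strftime("%Y-%m-%d"),
                    "specialty": draw_specialty(stage[rep_idx]),
                    "setting": "outpatient",
                    "region": region[rep_idx],
                }
            )
        )

    table = pd.concat(records, ignore_index=True)
    table = table.sort_values(["collection_date", "patient_id", "test_type"], kind="mergesort")
    table = table.reset_index(drop=True)

    truth = truth.assign(
        age=age,
        sex=sex_str,
        diabetes=diabetes,
        egfr_true=egfr_true,
        scr=scr,
        index_date=pd.Series(index_date).dt.strftime("%Y-%m-%d").to_numpy(),
    )
    return table, truth


def write_cohort(
    config: GeneratorConfig,
    records_path: Union[str, Path],
    truth_path: Optional[Union[str, Path]] = None,
) -> pd.DataFrame:
    """Generate and write the record CSV (plus optional latent-truth JSON)."""
    table, truth = generate_cohort(config)
    table.to_csv(records_path, index=False)
    if truth_path is not None:
        truth.to_json(truth_path, orient="records", indent=1)
    return table
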