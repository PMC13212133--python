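"""Metabolic and sleep phenotyping: fatty liver index, MASLD, sleep score.

Hepatic steatosis is inferred from the fatty liver index (FLI), a logistic
score over triglycerides, BMI, gamma-glutamyl transferase and waist
circumference; FLI >= 60 defines steatosis. MASLD is steatosis plus at
least one cardiometabolic criterion: type 2 diabetes, BMI >= 25, or at
least two items from a metabolic-abnormality list. A five-item composite
sleep score (chronotype, duration, insomnia, snoring, daytime sleepiness)
maps to healthy / intermediate / poor sleep patterns.

The FLI coefficients are bound to triglycerides in mg/dL and GGT in U/L;
``tg_mgdl_from_mmol`` converts from the mmol/L units common in UK lab data.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FLIComponents",
    "CardiometabolicProfile",
    "SleepProfile",
    "fatty_liver_index",
    "tg_mgdl_from_mmol",
    "tg_mmol_from_mgdl",
    "glucose_mgdl_from_mmol",
    "diagnose_masld",
    "sleep_score",
    "bmi_category",
    "phenotype_table",
    "FLI_STEATOSIS_CUTOFF",
]

FLI_STEATOSIS_CUTOFF = 60.0
TG_MGDL_PER_MMOL = 88.57     # triglyceride molar mass conversion
GLU_MGDL_PER_MMOL = 18.016   # glucose molar mass conversion


@dataclass(frozen=True)
class FLIComponents:
    """FLI inputs: TG mg/dL, BMI kg/m2, GGT U/L, waist circumference cm."""

    tg: float
    bmi: float
    ggt: float
    wc: float


@dataclass(frozen=True)
class CardiometabolicProfile:
    t2dm: bool
    bmi: float
    fasting_glucose: float  # mg/dL
    hba1c: float            # percent
    hdl: float              # mmol/L
    tg: float               # mmol/L
    sbp: float              # mmHg
    dbp: float              # mmHg
    antihypertensive_use: bool
    wc: float               # cm
    sex: str                # "male" / "female"
    insulin_resistance: bool | None = None  # unknown -> criterion not met


@dataclass(frozen=True)
class SleepProfile:
    chronotype: int          # questionnaire answer 1-4; 1-2 are morning types
    duration_hours: int
    insomnia: str            # never-rarely / sometimes / usually
    snoring: bool
    daytime_sleepiness: str  # never-rarely / sometimes / often


def fatty_liver_index(c: FLIComponents) -> float:
    """FLI = 100 * sigma(0.953 ln TG + 0.139 BMI + 0.718 ln GGT + 0.053 WC - 15.745).

    TG in mg/dL and GGT in U/L; a unit mismatch cannot be detected from the
    values alone. Result is strictly inside (0, 100).
    """
    for name, v in (("tg", c.tg), ("bmi", c.bmi), ("ggt", c.ggt), ("wc", c.wc)):
        if not v > 0:
            raise ValueError(f"FLI component {name} must be positive, got {v}")
    z = 0.953 * math.log(c.tg) + 0.139 * c.bmi + 0.718 * math.log(c.ggt) \
        + 0.053 * c.wc - 15.745
    return 100.0 / (1.0 + math.exp(-z))


def tg_mgdl_from_mmol(tg_mmol: float) -> float:
    """Triglycerides mmol/L -> mg/dL (x 88.57)."""
    if tg_mmol < 0:
        raise ValueError("triglyceride concentration cannot be negative")
    return tg_mmol * TG_MGDL_PER_MMOL


def tg_mmol_from_mgdl(tg_mgdl: float) -> float:
    if tg_mgdl < 0:
        raise ValueError("triglyceride concentration cannot be negative")
    return tg_mgdl / TG_MGDL_PER_MMOL


def glucose_mgdl_from_mmol(glu_mmol: float) -> float:
    """Glucose mmol/L -> mg/dL (x 18.016)."""
    if glu_mmol < 0:
        raise ValueError("glucose concentration cannot be negative")
    return glu_mmol * GLU_MGDL_PER_MMOL


def metabolic_criteria(p: CardiometabolicProfile) -> dict[str, bool]:
    """The six metabolic-abnormality items, each as an audit boolean."""
    if p.sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female' for sex-specific cutoffs")
    male = p.sex == "male"
    return {
        "insulin_resistance": bool(p.insulin_resistance)
        if p.insulin_resistance is not None else False,
        "prediabetes": p.fasting_glucose >= 100.0 or p.hba1c >= 5.7,
        "low_hdl": p.hdl < (1.03 if male else 1.29),
        "hypertriglyceridemia": p.tg >= 1.7,
        "hypertension": p.sbp >= 130.0 or p.dbp >= 85.0 or p.antihypertensive_use,
        "high_wc": p.wc >= (102.0 if male else 88.0),
    }


def diagnose_masld(fli: float, p: CardiometabolicProfile):
    """MASLD = steatosis (FLI >= 60) AND (T2DM OR BMI >= 25 OR >=2 metabolic items).

    Returns (masld, basis, criteria_met) where basis names the arm that
    fired ("t2dm" / "overweight" / "metabolic-count" / None) and
    criteria_met is the per-item audit dict.
    """
    criteria = metabolic_criteria(p)
    steatosis = fli >= FLI_STEATOSIS_CUTOFF
    basis = None
    if steatosis:
        if p.t2dm:
            basis = "t2dm"
        elif p.bmi >= 25.0:
            basis = "overweight"
        elif sum(criteria.values()) >= 2:
            basis = "metabolic-count"
    return basis is not None, basis, criteria


LOW_RISK_INSOMNIA = "never-rarely"
LOW_RISK_SLEEPINESS = ("never-rarely", "sometimes")


def sleep_score(s: SleepProfile):
    """Composite sleep score: one point per low-risk item, 0-5.

    Low-risk items: morning chronotype (answers 1-2), 7-8 h sleep, insomnia
    never/rarely, no snoring, daytime sleepiness never/rarely or sometimes.
    Pattern: healthy (>=4), intermediate (2-3), poor (<=1). Duration
    category: short (<7), normal (7-8), long (>=9).
    """
    for fname in ("chronotype", "duration_hours", "insomnia", "snoring",
                  "daytime_sleepiness"):
        if getattr(s, fname) is None:
            raise ValueError(f"missing sleep item: {fname}")
    dur = s.duration_hours
    if dur < 0:
        raise ValueError("sleep duration cannot be negative")
    if dur != int(dur):
        warnings.warn("non-integer sleep duration floored to whole hours")
        dur = int(dur)
    if dur < 7:
        duration_category = "short"
    elif dur <= 8:
        duration_category = "normal"
    else:
        duration_category = "long"
    points = {
        "chronotype": s.chronotype in (1, 2),
        "duration": duration_category == "normal",
        "insomnia": s.insomnia == LOW_RISK_INSOMNIA,
        "snoring": not s.snoring,
        "sleepiness": s.daytime_sleepiness in LOW_RISK_SLEEPINESS,
    }
    score = sum(points.values())
    if score >= 4:
        pattern = "healthy"
    elif score >= 2:
        pattern = "intermediate"
    else:
        pattern = "poor"
    return score, pattern, duration_category


def bmi_category(bmi: float) -> int:
    """BMI level: 1 < 18.5 <= 2 < 25 <= 3 < 30 <= 4 (lower bounds inclusive)."""
    if not bmi > 0:
        raise ValueError("BMI must be positive")
    if bmi < 18.5:
        return 1
    if bmi < 25.0:
        return 2
    if bmi < 30.0:
        return 3
    return 4


def phenotype_table(participants: pd.DataFrame, tg_units: str = "mmol") -> pd.DataFrame:
    """Add derived phenotype columns to a participant table.

    Expects columns: tg, bmi, ggt, wc, t2dm, fasting_glucose (mg/dL), hba1c,
    hdl, sbp, dbp, antihypertensive_use, sex, chronotype, duration_hours,
    insomnia, snoring, daytime_sleepiness. ``tg_units`` is "mmol" or "mgdl"
    for the triglyceride column; FLI always uses mg/dL internally while the
    MASLD hypertriglyceridemia cutoff uses mmol/L.
    """
    if tg_units not in ("mmol", "mgdl"):
        raise ValueError("tg_units must be 'mmol' or 'mgdl'")
    out = participants.copy()
    fli_vals, stea, masld, basis, bmi_lv = [], [], [], [], []
    scores, patterns, dur_cats = [], [], []
    for _, r in out.iterrows():
        tg_mmol = float(r["tg"]) if tg_units == "mmol" else tg_mmol_from_mgdl(float(r["tg"]))
        tg_mgdl = tg_mgdl_from_mmol(tg_mmol)
        fli = fatty_liver_index(FLIComponents(tg=tg_mgdl, bmi=float(r["bmi"]),
                                              ggt=float(r["ggt"]), wc=float(r["wc"])))
        prof = CardiometabolicProfile(
            t2dm=bool(r["t2dm"]), bmi=float(r["bmi"]),
            fasting_glucose=float(r["fasting_glucose"]), hba1c=float(r["hba1c"]),
            hdl=float(r["hdl"]), tg=tg_mmol, sbp=float(r["sbp"]), dbp=float(r["dbp"]),
            antihypertensive_use=bool(r["antihypertensive_use"]), wc=float(r["wc"]),
            sex=str(r["sex"]),
            insulin_resistance=None if "insulin_resistance" not in r
            else (None if pd.isna(r["insulin_resistance"]) else bool(r["insulin_resistance"])),
        )
        m, b, _ = diagnose_masld(fli, prof)
        sc, pat, dc = sleep_score(SleepProfile(
            chronotype=int(r["chronotype"]), duration_hours=int(r["duration_hours"]),
            insomnia=str(r["insomnia"]), snoring=bool(r["snoring"]),
            daytime_sleepiness=str(r["daytime_sleepiness"])))
        fli_vals.append(fli)
        stea.append(fli >= FLI_STEATOSIS_CUTOFF)
        masld.append(m)
        basis.append(b)
        bmi_lv.append(bmi_category(float(r["bmi"])))
        scores.append(sc)
        patterns.append(pat)
        dur_cats.append(dc)
    out["fli"] = fli_vals
    out["steatosis"] = stea
    out["masld_fli"] = masld
    out["masld_basis"] = basis
    out["bmi_level"] = bmi_lv
    out["sleep_score"] = scores
    out["sleep_pattern"] = patterns
    out["duration_category"] = dur_cats
    # a cohort generated with a planted outcome keeps its own masld column
    if "masld" not in out.columns:
        out["masld"] = out["masld_fli"]
    return out
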