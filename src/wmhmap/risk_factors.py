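"""Derivation of cerebrovascular risk (CVR) variables and the composite score.

Six categorical risk variables are derived from raw assessment fields:
hypertension risk (blood pressure over 140/90 mmHg or medicated),
hypercholesterolemia (medication flag), diagnosed diabetes, smoking score
from pack-years (0: <=10, 1: (10, 50], 2: >50), a sex-specific high
waist-to-hip-ratio indicator (>=0.9 men / >=0.85 women), and APOE-e4 allele
count. Their sum is the composite CVR score on a 0-8 scale. Missing values
are carried as NaN sentinels and removed by an explicit complete-case
filter; nothing is silently zero-filled.

All derivation functions accept scalars or array-likes and are NaN-aware.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "RiskFactorProfile",
    "DEFAULT_EDUCATION_YEARS",
    "derive_hypertension_indicator",
    "compute_pack_years_and_smoking_score",
    "derive_whr_indicator",
    "derive_apoe_status",
    "map_education_years",
    "assemble_risk_profile",
    "derive_risk_table",
    "complete_case_filter",
]

#: Qualification -> years of education, ISCED-style. The six year values
#: are the levels observed in the cohort summary (7, 10, 13, 15, 19, 20).
DEFAULT_EDUCATION_YEARS: dict[str, int] = {
    "none": 7,
    "cses_or_equivalent": 10,
    "o_levels_gcses": 10,
    "a_levels": 13,
    "other_professional": 15,
    "nvq_hnd_hnc": 19,
    "degree": 20,
}

APOE_GENOTYPES = ("e2/e2", "e2/e3", "e2/e4", "e3/e3", "e3/e4", "e4/e4")


@dataclass
class RiskFactorProfile:
    """Per-subject derived risk variables and composite score."""

    hypertension: float
    hypercholesterolemia: float
    diabetes: float
    pack_years: float
    smoking_score: float
    whr: float
    whr_indicator: float
    apoe_status: float
    education_years: float
    cvr_score: float

    @property
    def complete(self) -> bool:
        vals = [self.hypertension, self.hypercholesterolemia, self.diabetes,
                self.smoking_score, self.whr_indicator, self.apoe_status]
        return not any(pd.isna(v) for v in vals)


def _asfloat(x):
    """Coerce scalar/array input to float ndarray; None/NA -> NaN."""
    arr = np.asarray(pd.array(np.atleast_1d(x), dtype="Float64").to_numpy(
        dtype=float, na_value=np.nan))
    return arr


def _scalar_in(*args) -> bool:
    return all(np.ndim(a) == 0 for a in args)


def _out(arr, scalar):
    return float(arr[0]) if scalar else arr


def derive_hypertension_indicator(sbp_1, sbp_2, dbp_1, dbp_2, bp_medication):
    """Hypertension risk: mean BP over 140/90 mmHg or on BP medication.

    Uses the mean of the two readings per channel (one reading suffices if
    the other is missing). Three-valued logic: 1 if any condition is known
    true; 0 only if all conditions are known false; NaN otherwise.
    The rule is strict ("over"): exactly 140/90 codes 0.
    """
    import warnings

    scalar = _scalar_in(sbp_1, sbp_2, dbp_1, dbp_2, bp_medication)
    s1, s2, d1, d2, med = map(_asfloat, (sbp_1, sbp_2, dbp_1, dbp_2, bp_medication))
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pairs
        sbp = np.nanmean(np.stack([s1, s2]), axis=0)
        dbp = np.nanmean(np.stack([d1, d2]), axis=0)
        high_s = sbp > 140.0
        high_d = dbp > 90.0
    on_med = med == 1
    known = [~np.isnan(sbp), ~np.isnan(dbp), ~np.isnan(med)]
    conds = [high_s, high_d, on_med]
    any_true = np.zeros(s1.shape, dtype=bool)
    all_known_false = np.ones(s1.shape, dtype=bool)
    for c, k in zip(conds, known):
        any_true |= c & k
        all_known_false &= k & ~c
    out = np.where(any_true, 1.0, np.where(all_known_false, 0.0, np.nan))
    return _out(out, scalar)


def compute_pack_years_and_smoking_score(cigs_per_day, age_started=None,
                                         age_stopped_or_current=None,
                                         abstinence_years=None):
    """Pack-years = (cigarettes/day / 20) x years smoked; 3-level score.

    Years smoked run from the age smoking started to the age stopped (or the
    current age for current smokers), reduced by recorded abstinence when it
    exceeds half a year. Score: 0 for <=10 pack-years (non-smokers), 1 for
    (10, 50], 2 for >50 (heavy smokers). Never-smokers (0/day) score 0
    without needing the age fields.
    """
    scalar = _scalar_in(cigs_per_day, age_started, age_stopped_or_current)
    cigs = _asfloat(cigs_per_day)
    start = _asfloat(age_started if age_started is not None else np.nan)
    stop = _asfloat(age_stopped_or_current
                    if age_stopped_or_current is not None else np.nan)
    abst = _asfloat(abstinence_years if abstinence_years is not None else 0.0)
    start, stop, abst = (np.broadcast_to(a, cigs.shape).astype(float)
                         for a in (start, stop, abst))
    abst = np.where(np.isnan(abst), 0.0, abst)

    years = stop - start
    smoker = cigs > 0
    if np.any(smoker & (years < 0)):
        raise ValueError("negative smoking duration (age stopped < age started)")
    years = np.where(abst > 0.5, years - abst, years)
    years = np.clip(years, 0.0, None)
    pack_years = np.where(smoker, cigs / 20.0 * years, 0.0)
    pack_years = np.where(np.isnan(cigs) | (smoker & np.isnan(years)),
                          np.nan, pack_years)
    score = np.where(pack_years <= 10.0, 0.0,
                     np.where(pack_years <= 50.0, 1.0, 2.0))
    score = np.where(np.isnan(pack_years), np.nan, score)
    if scalar:
        return float(pack_years[0]), float(score[0])
    return pack_years, score


_SEX_CODES = {"female": 1.0, "f": 1.0, "male": 0.0, "m": 0.0,
              "1": 1.0, "0": 0.0, "1.0": 1.0, "0.0": 0.0,
              "true": 1.0, "false": 0.0}


def _female_mask(sex):
    ser = pd.Series(np.atleast_1d(np.asarray(sex, dtype=object)).ravel())
    na = ser.isna()
    norm = ser.astype(str).str.strip().str.lower()
    out = norm.map(_SEX_CODES)
    bad = out.isna() & ~na
    if bad.any():
        raise ValueError(f"unrecognised sex value {ser[bad].iloc[0]!r}")
    return out.to_numpy(dtype=float)


def derive_whr_indicator(waist_cm, hip_cm, sex, inclusive: bool = True):
    """Waist-to-hip ratio and sex-specific high-WHR indicator.

    Threshold 0.9 for men, 0.85 for women, inclusive (>=) by WHO convention;
    ``inclusive=False`` switches to a strict rule.
    """
    scalar = _scalar_in(waist_cm, hip_cm, sex)
    waist, hip = _asfloat(waist_cm), _asfloat(hip_cm)
    if np.any(hip == 0):
        raise ValueError("hip circumference of zero")
    if np.any((waist <= 0) & ~np.isnan(waist)) or np.any((hip < 0) & ~np.isnan(hip)):
        raise ValueError("circumferences must be positive")
    female = np.broadcast_to(_female_mask(sex), waist.shape)
    whr = waist / hip
    thr = np.where(female == 1, 0.85, 0.90)
    ind = (whr >= thr) if inclusive else (whr > thr)
    ind = np.where(np.isnan(whr) | np.isnan(female), np.nan, ind.astype(float))
    if scalar:
        return float(whr[0]), float(ind[0])
    return whr, ind


def _normalise_genotype(g: str) -> str:
    s = str(g).strip().lower().replace("ε", "e").replace(" ", "")
    return s


def derive_apoe_status(apoe_genotype, e2e4_policy: str = "count"):
    """Number of APOE e4 alleles: 0, 1 (heterozygous) or 2 (homozygous).

    The e2/e4 diplotype carries one e4 allele and is counted as status 1 by
    default; ``e2e4_policy="exclude"`` marks such subjects missing instead.
    """
    if e2e4_policy not in ("count", "exclude"):
        raise ValueError(f"unknown e2/e4 policy {e2e4_policy!r}")
    scalar = np.ndim(apoe_genotype) == 0
    ser = pd.Series(np.atleast_1d(np.asarray(apoe_genotype, dtype=object)).ravel())
    na = ser.isna()
    norm = (ser.astype(str).str.strip().str.lower()
            .str.replace("ε", "e", regex=False).str.replace(" ", "", regex=False))
    bad = ~norm.isin(APOE_GENOTYPES) & ~na
    if bad.any():
        raise ValueError(f"unknown APOE genotype {ser[bad].iloc[0]!r}")
    out = norm.str.count("4").astype(float)
    out[na] = np.nan
    if e2e4_policy == "exclude":
        out[norm == "e2/e4"] = np.nan
    return _out(out.to_numpy(), scalar)


def map_education_years(qualification, mapping: Mapping[str, int] | None = None):
    """Map a qualification category to years of education.

    Unmapped categories yield the missing-value marker (NaN), never an error,
    so downstream complete-case filtering can count them.
    """
    mapping = {str(k).strip().lower(): float(v) for k, v in
               (DEFAULT_EDUCATION_YEARS if mapping is None else mapping).items()}
    scalar = np.ndim(qualification) == 0
    ser = pd.Series(np.atleast_1d(np.asarray(qualification, dtype=object)).ravel())
    out = ser.astype(str).str.strip().str.lower().map(mapping)
    out[ser.isna()] = np.nan
    return _out(out.to_numpy(dtype=float), scalar)


def assemble_risk_profile(record: Mapping, education_mapping=None,
                          e2e4_policy: str = "count",
                          whr_inclusive: bool = True) -> RiskFactorProfile:
    """Derive the full risk profile for one subject record.

    ``record`` maps raw field names (sbp_1, sbp_2, dbp_1, dbp_2,
    bp_medication, chol_medication, diabetes_diagnosed, cigs_per_day,
    age_started_smoking, age_stopped_smoking, abstinence_years, age,
    waist_cm, hip_cm, sex, apoe_genotype, qualification) to values. The
    composite score is NaN whenever any of its six components is missing;
    incomplete profiles are consumed by :func:`complete_case_filter`.
    """
    g = lambda k, default=np.nan: record.get(k, default)
    htn = derive_hypertension_indicator(
        g("sbp_1"), g("sbp_2"), g("dbp_1"), g("dbp_2"), g("bp_medication"))
    chol = _asfloat(g("chol_medication"))[0]
    diab = _asfloat(g("diabetes_diagnosed"))[0]
    stopped = g("age_stopped_smoking")
    if stopped is None or pd.isna(stopped):
        stopped = g("age")  # current smoker: years run to the assessment age
    pack_years, smoke = compute_pack_years_and_smoking_score(
        g("cigs_per_day"), g("age_started_smoking"), stopped,
        g("abstinence_years"))
    whr, whr_ind = derive_whr_indicator(
        g("waist_cm"), g("hip_cm"), g("sex"), inclusive=whr_inclusive)
    apoe = derive_apoe_status(g("apoe_genotype"), e2e4_policy=e2e4_policy)
    edu = map_education_years(g("qualification"), education_mapping)
    components = np.array([htn, chol, diab, smoke, whr_ind, apoe])
    cvr = np.nan if np.isnan(components).any() else float(components.sum())
    return RiskFactorProfile(
        hypertension=htn, hypercholesterolemia=chol, diabetes=diab,
        pack_years=pack_years, smoking_score=smoke, whr=whr,
        whr_indicator=whr_ind, apoe_status=apoe, education_years=edu,
        cvr_score=cvr)


def derive_risk_table(raw: pd.DataFrame, education_mapping=None,
                      e2e4_policy: str = "count",
                      whr_inclusive: bool = True) -> pd.DataFrame:
    """Vectorised risk-profile derivation for a whole raw assessment table.

    Returns a new table of derived columns indexed like ``raw``; raw columns
    ``age``, ``sex`` and ``head_size`` (when present) are carried through,
    with sex recoded to a 0/1 ``female`` column (men are the baseline level).
    """
    out = pd.DataFrame(index=raw.index)
    if "subject_id" in raw.columns:
        out["subject_id"] = raw["subject_id"]
    for col in ("age", "head_size", "reaction_time_ms"):
        if col in raw.columns:
            out[col] = raw[col].astype(float)
    out["female"] = _female_mask(raw["sex"].to_numpy())
    out["hypertension"] = derive_hypertension_indicator(
        raw["sbp_1"], raw["sbp_2"], raw["dbp_1"], raw["dbp_2"],
        raw["bp_medication"])
    out["hypercholesterolemia"] = _asfloat(raw["chol_medication"])
    out["diabetes"] = _asfloat(raw["diabetes_diagnosed"])
    stopped = raw["age_stopped_smoking"].astype(float)
    stopped = stopped.where(stopped.notna(), raw["age"].astype(float))
    abst = (raw["abstinence_years"] if "abstinence_years" in raw.columns
            else pd.Series(0.0, index=raw.index))
    py, sc = compute_pack_years_and_smoking_score(
        raw["cigs_per_day"], raw["age_started_smoking"], stopped, abst)
    out["pack_years"], out["smoking_score"] = py, sc
    out["whr"], out["whr_indicator"] = derive_whr_indicator(
        raw["waist_cm"], raw["hip_cm"], raw["sex"].to_numpy(),
        inclusive=whr_inclusive)
    out["apoe_status"] = derive_apoe_status(
        raw["apoe_genotype"].to_numpy(), e2e4_policy=e2e4_policy)
    if "qualification" in raw.columns:
        out["education_years"] = map_education_years(
            raw["qualification"].to_numpy(), education_mapping)
    comp = out[["hypertension", "hypercholesterolemia", "diabetes",
                "smoking_score", "whr_indicator", "apoe_status"]].to_numpy()
    cvr = comp.sum(axis=1)
    cvr[np.isnan(comp).any(axis=1)] = np.nan
    out["cvr_score"] = cvr
    return out


def complete_case_filter(table: pd.DataFrame, required_columns):
    """Drop rows with any missing required value; report removals per column.

    A row missing several variables is counted once in the removal total but
    appears in every per-column count it is missing from. Idempotent. An
    empty result warns rather than errors.
    """
    import warnings

    missing_cols = [c for c in required_columns if c not in table.columns]
    if missing_cols:
        raise KeyError(f"required columns absent from table: {missing_cols}")
    isna = table[list(required_columns)].isna()
    report = {
        "per_column": {c: int(isna[c].sum()) for c in required_columns},
        "n_input": int(len(table)),
        "n_removed": int(isna.any(axis=1).sum()),
        "n_kept": int((~isna.any(axis=1)).sum()),
    }
    filtered = table.loc[~isna.any(axis=1)].copy()
    if len(filtered) == 0 and len(table) > 0:
        warnings.warn("complete-case filter removed every row", stacklevel=2)
    return filtered, report
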