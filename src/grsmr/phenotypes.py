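"""Derivation of analysis variables from raw questionnaire-style fields.

Covers the cohort-exclusion cascade, the ±3.29 z-score outlier rule for
activity durations, the IPAQ short-form MET score, the qualification →
education-leaving-age mapping (15–21 years), the job-satisfaction recode
(missing when unemployed), log transforms of MET and BMI, and z-scoring of
the three exposures on the analysis sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import FLAG_ORDER

__all__ = [
    "DEFAULT_EDUCATION_MAPPING",
    "apply_cohort_exclusions",
    "exclude_duration_outliers",
    "compute_met_score",
    "map_education_years",
    "recode_job_satisfaction",
    "standardize",
    "derive_phenotypes",
    "DerivedPhenotypes",
]

#: Qualification category → assigned age at leaving education (years).
#: All assigned ages lie within [15, 21]; overridable via config.
DEFAULT_EDUCATION_MAPPING = {
    "none": 15,
    "cse_gcse": 16,
    "a_level": 18,
    "nvq_hnd": 19,
    "other_professional": 20,
    "degree": 21,
}

#: Z-score magnitude beyond which an activity duration is an extreme outlier.
OUTLIER_Z = 3.29

#: MET-minutes/week coefficients (IPAQ short form).
MET_WALK, MET_MODERATE, MET_VIGOROUS = 3.3, 4.0, 8.0

_MISSING_CODES = {"do not know", "prefer not to answer", "-1", "-3"}


def apply_cohort_exclusions(cohort: pd.DataFrame
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mark rows failing any exclusion criterion as ineligible.

    Flags are applied in the cascade order (consent withdrawal, sex
    mismatch, relatedness, ethnicity, ICD-10 mental/neurological history,
    missing neuroticism); a multiply-flagged row is attributed to the
    earliest-listed criterion.  Returns the cohort with an
    ``analysis_eligible`` column plus a per-criterion attrition table.
    """
    missing = [f for f in FLAG_ORDER if f not in cohort.columns]
    if missing:
        raise ValueError(f"missing exclusion flag column(s): {missing}")
    out = cohort.copy()
    remaining = pd.Series(True, index=out.index)
    rows = []
    for flag in FLAG_ORDER:
        hit = remaining & out[flag].astype(bool)
        rows.append({"criterion": flag, "n_removed": int(hit.sum()),
                     "n_remaining": int((remaining & ~hit).sum())})
        remaining &= ~hit
    out["analysis_eligible"] = remaining
    attrition = pd.DataFrame(rows)
    return out, attrition


def exclude_duration_outliers(cohort: pd.DataFrame, z_threshold: float = OUTLIER_Z,
                              columns=("walk_min", "mod_min", "vig_min"),
                              restrict_to_eligible: bool = True
                              ) -> tuple[pd.DataFrame, pd.Series]:
    """Set extreme activity durations (|z| > 3.29 on the raw scale) missing.

    The z-score of each duration is computed once over its non-missing
    (eligible, if marked) rows; values strictly beyond the threshold are set
    missing while the sample is retained for other analyses.  A column with
    zero variance yields no exclusions.  Returns the cohort and the count
    of removals per column.
    """
    out = cohort.copy()
    if restrict_to_eligible and "analysis_eligible" in out.columns:
        scope = out["analysis_eligible"].astype(bool)
    else:
        scope = pd.Series(True, index=out.index)
    counts = {}
    for col in columns:
        vals = out.loc[scope, col].astype(float)
        ok = vals.notna()
        sd = vals[ok].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(f"{col}: zero variance, no outliers excluded")
            counts[col] = 0
            continue
        z = (vals - vals[ok].mean()) / sd
        bad = z.abs() > z_threshold
        out.loc[bad[bad].index, col] = np.nan
        counts[col] = int(bad.sum())
    return out, pd.Series(counts, name="n_outliers_removed")


def compute_met_score(walk_days, walk_min, mod_days, mod_min,
                      vig_days, vig_min):
    """Weekly MET score: 3.3·walk + 4.0·moderate + 8.0·vigorous minutes.

    Days count questionnaire days with ≥10-minute bouts and must lie in
    [0, 7]; durations are minutes per day.  Any missing input produces a
    missing score; negative inputs raise.
    """
    arrs = [np.asarray(a, dtype=float) for a in
            (walk_days, walk_min, mod_days, mod_min, vig_days, vig_min)]
    for a, name in zip(arrs, ("walk_days", "walk_min", "mod_days",
                              "mod_min", "vig_days", "vig_min")):
        if np.nanmin(a, initial=0) < 0:
            raise ValueError(f"negative values in {name}")
    for a, name in zip(arrs[::2], ("walk_days", "mod_days", "vig_days")):
        if np.nanmax(a, initial=0) > 7:
            raise ValueError(f"{name} above 7 days/week")
    wd, wm, md, mm, vd, vm = arrs
    met = wd * wm * MET_WALK + md * mm * MET_MODERATE + vd * vm * MET_VIGOROUS
    return met if met.ndim else float(met)


def map_education_years(categories, mapping: dict | None = None):
    """Map highest-qualification categories to education-leaving age.

    Unknown categories map to missing with a warning.
    """
    mapping = dict(DEFAULT_EDUCATION_MAPPING if mapping is None else mapping)
    bad = [f"{cat}: {age}" for cat, age in mapping.items()
           if not 15 <= age <= 21]
    if bad:
        raise ValueError(f"education ages outside [15, 21]: {bad}")
    ser = pd.Series(categories).astype(object)
    out = ser.map(mapping)
    unknown = ser.notna() & out.isna()
    if unknown.any():
        labels = sorted(set(ser[unknown].astype(str)))
        warnings.warn(f"unknown qualification categories set missing: {labels}")
    return out.astype(float).to_numpy() if not np.isscalar(categories) \
        else float(out.iloc[0]) if out.notna().iloc[0] else np.nan


def recode_job_satisfaction(raw, employed):
    """Recode job satisfaction: missing when unemployed or answer declined.

    ``raw`` values must be in {1..6} or a recognised missing-like code
    ("do not know", "prefer not to answer", negative sentinel codes).
    """
    ser = pd.Series(raw).astype(object)
    emp = pd.Series(employed).astype(float)

    def _one(v):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return np.nan
        if str(v).strip().lower() in _MISSING_CODES:
            return np.nan
        x = float(v)
        if x not in (1.0, 2.0, 3.0, 4.0, 5.0, 6.0):
            raise ValueError(f"job satisfaction value out of range: {v!r}")
        return x

    out = ser.map(_one).astype(float)
    out[emp.fillna(0) == 0] = np.nan
    return out.to_numpy()


def standardize(values, ddof: int = 1):
    """Z-score over non-missing entries using the sample SD (n−1 divisor).

    Missing entries stay missing.  Raises on fewer than two non-missing
    values or zero variance.
    """
    x = np.asarray(values, dtype=float)
    ok = ~np.isnan(x)
    if ok.sum() < 2:
        raise ValueError("need at least two non-missing values")
    sd = np.std(x[ok], ddof=ddof)
    if sd == 0:
        raise ValueError("zero variance: cannot standardise")
    out = np.full_like(x, np.nan)
    out[ok] = (x[ok] - x[ok].mean()) / sd
    return out


@dataclass
class DerivedPhenotypes:
    """Derived analysis table plus attrition bookkeeping."""

    table: pd.DataFrame
    attrition: pd.DataFrame
    outlier_counts: pd.Series = field(default_factory=pd.Series)

    @property
    def n_eligible(self) -> int:
        return int(self.table["analysis_eligible"].sum())


def derive_phenotypes(cohort: pd.DataFrame,
                      education_mapping: dict | None = None,
                      outlier_z: float = OUTLIER_Z) -> DerivedPhenotypes:
    """Full derivation: exclusions → outlier rule → MET/education/outcome →
    log transforms → z-scores on the analysis sample.

    z-scores (``z_neuroticism``, ``z_education``, ``z_met``) are computed
    after cohort exclusions and outlier handling, over non-missing eligible
    rows only; MET and BMI are natural-log transformed first (``log(met+1)``
    so zero activity is representable).
    """
    out, attrition = apply_cohort_exclusions(cohort)
    out, outlier_counts = exclude_duration_outliers(out, z_threshold=outlier_z)

    out["met_score"] = compute_met_score(
        out["walk_days"], out["walk_min"], out["mod_days"], out["mod_min"],
        out["vig_days"], out["vig_min"])
    out["log_met"] = np.log1p(out["met_score"])
    out["log_bmi"] = np.log(out["bmi"].astype(float))
    out["education_years"] = map_education_years(
        out["qualification"], education_mapping)

    if out["job_satisfaction"].dropna().isin([1, 2, 3, 4, 5, 6]).all() \
            and out["job_satisfaction"].notna().any():
        out["job_satisfaction"] = recode_job_satisfaction(
            out["job_satisfaction"], out["employed"])
    else:  # continuous latent scale: enforce the unemployed-missing rule only
        js = out["job_satisfaction"].astype(float)
        js[out["employed"] == 0] = np.nan
        out["job_satisfaction"] = js

    elig = out["analysis_eligible"].astype(bool)
    for src, dst in (("neuroticism", "z_neuroticism"),
                     ("education_years", "z_education"),
                     ("log_met", "z_met")):
        out[dst] = np.nan
        out.loc[elig, dst] = standardize(out.loc[elig, src])
    return DerivedPhenotypes(out, attrition, outlier_counts)
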