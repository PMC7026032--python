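"""Per-variant instrument-validity screening and sensitivity risk scores.

Each candidate instrument is tested twice on the analysis sample: for
association with its own trait (``trait ~ SNP + age + sex``) and for direct
association with the outcome conditional on the trait
(``outcome ~ SNP + trait + age + sex + centre + TDI``).  A variant is
retained only if it shows nominal association with its trait
(p < 0.05) and no nominal association with the outcome (p ≥ 0.05); the
sensitivity GRS is the unweighted score over retained variants.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .causal import build_design
from .containers import GenotypeMatrix, InstrumentSet
from .grs import GRSResult, compute_unweighted_grs

__all__ = ["TRAIT_Z_COLUMN", "screen_variant", "screen_instruments",
           "build_sensitivity_grs"]

#: Analysis z-score column for each trait panel.
TRAIT_Z_COLUMN = {
    "neuroticism": "z_neuroticism",
    "education": "z_education",
    "activity": "z_met",
}

_FULL_ADJ = ("age", "sex", "centre", "tdi")
_MINIMAL_ADJ = ("age", "sex")


def _slope_p(y: np.ndarray, x: np.ndarray, W: np.ndarray) -> float:
    """Two-sided t-test p-value for x in the model y ~ x + W."""
    Z = np.column_stack([x, W])
    beta, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    if rank < Z.shape[1]:
        return np.nan
    resid = y - Z @ beta
    n, k = Z.shape
    sigma2 = float(resid @ resid) / (n - k)
    se = np.sqrt(sigma2 * np.linalg.inv(Z.T @ Z)[0, 0])
    return float(2.0 * stats.t.sf(abs(beta[0] / se), n - k))


def screen_variant(dosage, trait, outcome, covariates: pd.DataFrame,
                   alpha_trait: float = 0.05, alpha_outcome: float = 0.05,
                   adjustment: str = "full") -> dict:
    """Validity screen for one variant.

    Returns p-values of the trait and conditional-outcome tests and the
    inclusion decision with its reason code (``weak_with_trait`` |
    ``outcome_associated`` | ``retained``).  Zero dosage variance on the
    analysis rows excludes the variant as ``weak_with_trait``.
    """
    adj = _FULL_ADJ if adjustment == "full" else _MINIMAL_ADJ
    adj = [c for c in adj if c in covariates.columns]
    df = covariates.copy()
    df["_snp"] = np.asarray(dosage, dtype=float)
    df["_trait"] = np.asarray(trait, dtype=float)
    df["_out"] = np.asarray(outcome, dtype=float)

    tr = df.dropna(subset=["_snp", "_trait", "age", "sex"])
    if len(tr) < 10:
        raise ValueError("fewer than 10 complete rows for the trait screen")
    if tr["_snp"].std() == 0:
        return {"p_trait": np.nan, "p_outcome": np.nan, "retained": False,
                "reason": "weak_with_trait", "n_trait": len(tr), "n_outcome": 0}
    W = build_design(tr, ("age", "sex")).to_numpy(dtype=float)
    p_trait = _slope_p(tr["_trait"].to_numpy(), tr["_snp"].to_numpy(), W)

    oc = df.dropna(subset=["_snp", "_trait", "_out", *adj])
    W2 = np.column_stack([
        oc["_trait"].to_numpy(dtype=float),
        build_design(oc, adj).to_numpy(dtype=float)])
    p_out = _slope_p(oc["_out"].to_numpy(), oc["_snp"].to_numpy(), W2)

    if not p_trait < alpha_trait:
        decision, reason = False, "weak_with_trait"
    elif p_out < alpha_outcome:
        decision, reason = False, "outcome_associated"
    else:
        decision, reason = True, "retained"
    return {"p_trait": p_trait, "p_outcome": p_out, "retained": decision,
            "reason": reason, "n_trait": len(tr), "n_outcome": len(oc)}


def screen_instruments(genotypes: GenotypeMatrix, cohort: pd.DataFrame,
                       instruments: InstrumentSet,
                       outcome: str = "job_satisfaction",
                       alpha: float = 0.05, bonferroni: bool = False,
                       adjustment: str = "full") -> pd.DataFrame:
    """Screen every instrument variant; one row per variant.

    ``bonferroni=True`` divides the nominal threshold by the panel size for
    both tests (off by default: the screen is nominal by design).
    """
    if "analysis_eligible" in cohort.columns:
        cohort = cohort[cohort["analysis_eligible"].astype(bool)]
    rows = []
    for trait in instruments.traits:
        panel = instruments.for_trait(trait)
        zcol = TRAIT_Z_COLUMN[trait]
        a = alpha / len(panel) if bonferroni else alpha
        for vid in panel["variant_id"]:
            if vid not in genotypes.dosages.columns:
                continue
            dos = genotypes.dosages[vid].reindex(cohort.index)
            res = screen_variant(dos, cohort[zcol], cohort[outcome],
                                 cohort, alpha_trait=a, alpha_outcome=a,
                                 adjustment=adjustment)
            rows.append({"variant_id": vid, "trait": trait, **res})
    return pd.DataFrame(rows)


def build_sensitivity_grs(screening: pd.DataFrame, genotypes: GenotypeMatrix,
                          instruments: InstrumentSet,
                          missing: str = "impute") -> dict[str, GRSResult]:
    """Unweighted GRS per trait over retained variants only.

    Raises if a trait panel retains no variants.
    """
    out = {}
    for trait in instruments.traits:
        keep = screening.loc[
            (screening["trait"] == trait) & screening["retained"],
            "variant_id"]
        if keep.empty:
            raise ValueError(f"no variants retained for trait {trait!r}")
        sub = InstrumentSet(
            instruments.for_trait(trait)
            .set_index("variant_id").loc[keep].reset_index())
        out[trait] = compute_unweighted_grs(genotypes, sub, trait,
                                            missing=missing)
    return out
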