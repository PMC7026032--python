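"""Unweighted genetic risk scores from effect-allele dosages.

Reading dosage tables (TSV dialect or minimal VCF 4.2 via ``cyvcf2``),
per-variant call-rate QC (default: drop below 90%), effect-allele alignment
(re-orienting dosages counted on the other allele, dropping ambiguous-strand
pairs in strict mode), unweighted risk-allele counting with configurable
missing-dosage handling, and incremental variance explained (R² of the trait
on the GRS over an age+sex baseline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, InstrumentSet

__all__ = [
    "GRSResult",
    "VarianceExplained",
    "read_genotypes",
    "variant_qc",
    "align_effect_alleles",
    "compute_unweighted_grs",
    "variance_explained",
]

_AMBIGUOUS = ({"A", "T"}, {"C", "G"})


@dataclass
class GRSResult:
    """Per-sample unweighted risk-allele count for one trait panel."""

    scores: pd.Series
    trait: str
    n_variants_used: int
    call_rate: pd.Series = field(default_factory=pd.Series)
    missing_mode: str = "impute"

    def __post_init__(self) -> None:
        upper = 2 * self.n_variants_used
        vals = self.scores.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0) < -1e-9 or np.nanmax(vals, initial=0) > upper + 1e-9:
            raise ValueError("scores outside [0, 2 * n_variants_used]")


@dataclass
class VarianceExplained:
    """Incremental R² of a trait on its GRS over an age+sex baseline."""

    r2: float
    beta: float
    se: float
    n: int


def read_genotypes(path, fmt: str = "tsv", variant_path=None) -> GenotypeMatrix:
    """Read a genotype matrix from dosage TSV or minimal VCF 4.2.

    Both dialects require the variant side-car (``variant_id effect_allele
    other_allele eaf trait``).  For VCF, GT allele counts are converted to
    effect-allele dosage by orienting against the side-car: if the side-car's
    effect allele is the record's ALT the ALT count is used directly,
    if it is the REF the count is complemented, otherwise the alleles
    mismatch and reading fails.
    """
    if variant_path is None:
        raise ValueError("variant side-car path is required")
    if fmt == "tsv":
        return GenotypeMatrix.from_tsv(path, variant_path)
    if fmt != "vcf":
        raise ValueError(f"unknown genotype format: {fmt!r}")

    from cyvcf2 import VCF

    var = pd.read_csv(variant_path, sep="\t").set_index("variant_id")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, data = [], []
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    alt_count = np.array([0.0, 1.0, np.nan, 2.0])
    for rec in vcf:
        vid = rec.ID
        if vid not in var.index:
            warnings.warn(f"VCF variant {vid} absent from side-car; skipped")
            continue
        meta = var.loc[vid]
        alt = rec.ALT[0] if rec.ALT else None
        dos = alt_count[rec.gt_types]
        if meta.effect_allele == alt and meta.other_allele == rec.REF:
            pass
        elif meta.effect_allele == rec.REF and meta.other_allele == alt:
            dos = 2.0 - dos
        else:
            raise ValueError(
                f"allele mismatch for {vid}: VCF {rec.REF}/{alt} vs side-car "
                f"{meta.effect_allele}/{meta.other_allele}")
        cols.append(vid)
        data.append(dos)
    dosages = pd.DataFrame(
        np.column_stack(data), columns=cols,
        index=pd.Index(samples, name="sample_id"))
    return GenotypeMatrix(dosages, var.loc[cols].reset_index())


def variant_qc(genotypes: GenotypeMatrix, min_call_rate: float = 0.90
               ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop variants with call rate strictly below ``min_call_rate``.

    A variant at exactly the threshold is kept.  Returns the filtered matrix
    and a removal log with per-variant call rates.
    """
    if not 0.0 < min_call_rate <= 1.0:
        raise ValueError("min_call_rate must be in (0, 1]")
    rates = genotypes.call_rate()
    failed = rates[rates < min_call_rate]
    if len(failed) == genotypes.n_variants:
        raise ValueError("all variants failed the call-rate filter")
    log = pd.DataFrame({
        "variant_id": failed.index,
        "call_rate": failed.to_numpy(),
        "reason": "call_rate_below_threshold",
    })
    kept = [v for v in genotypes.variant_ids if v not in set(failed.index)]
    return genotypes.subset(kept), log


def align_effect_alleles(genotypes: GenotypeMatrix, instruments: InstrumentSet,
                         strict: bool = True) -> GenotypeMatrix:
    """Re-express dosages as counts of each instrument's risk allele.

    When the genotype file counts the other allele the dosage is
    complemented (``2 − dosage``) and the metadata swapped.  Variants whose
    allele pair does not match the instrument record are dropped with a
    warning (no strand-flip guessing); ambiguous-strand pairs (A/T, C/G)
    are dropped in strict mode.
    """
    inst = instruments.table.set_index("variant_id")
    dosages = genotypes.dosages.copy()
    variants = genotypes.variants.copy()
    keep = []
    for vid in genotypes.variant_ids:
        if vid not in inst.index:
            keep.append(vid)  # not an instrument: leave untouched
            continue
        rec, meta = inst.loc[vid], variants.loc[vid]
        pair = {meta.effect_allele, meta.other_allele}
        if strict and pair in _AMBIGUOUS:
            warnings.warn(f"{vid}: ambiguous-strand alleles, dropped")
            continue
        if (meta.effect_allele, meta.other_allele) == (rec.effect_allele,
                                                       rec.other_allele):
            keep.append(vid)
        elif (meta.other_allele, meta.effect_allele) == (rec.effect_allele,
                                                         rec.other_allele):
            dosages[vid] = 2.0 - dosages[vid]
            variants.loc[vid, ["effect_allele", "other_allele"]] = [
                rec.effect_allele, rec.other_allele]
            variants.loc[vid, "eaf"] = 1.0 - float(meta.eaf)
            keep.append(vid)
        else:
            warnings.warn(f"{vid}: allele pair mismatch with instrument "
                          "record, dropped")
    return GenotypeMatrix(dosages[keep], variants.loc[keep])


def compute_unweighted_grs(genotypes: GenotypeMatrix,
                           instruments: InstrumentSet, trait: str,
                           missing: str = "impute") -> GRSResult:
    """Sum risk-allele dosages over one trait panel.

    ``missing='impute'`` replaces a missing dosage with twice the in-sample
    effect-allele frequency (so scores may be real-valued);
    ``missing='drop'`` sums available dosages only.  Instrument variants
    absent from the genotype matrix are skipped with a warning.
    """
    if missing not in ("impute", "drop"):
        raise ValueError("missing must be 'impute' or 'drop'")
    panel = instruments.for_trait(trait)
    present = [v for v in panel["variant_id"] if v in genotypes.dosages.columns]
    absent = sorted(set(panel["variant_id"]) - set(present))
    if absent:
        warnings.warn(f"{trait}: {len(absent)} instrument variant(s) absent "
                      f"from genotypes, skipped: {absent[:5]}")
    if not present:
        raise ValueError(f"empty panel for trait {trait!r}")
    d = genotypes.dosages[present].to_numpy(dtype=float)
    call_rate = genotypes.dosages[present].notna().mean(axis=0)
    if missing == "impute":
        eaf = np.nanmean(d, axis=0) / 2.0
        idx = np.where(np.isnan(d))
        d[idx] = 2.0 * eaf[idx[1]]
        scores = d.sum(axis=1)
    else:
        scores = np.nansum(d, axis=1)
    return GRSResult(pd.Series(scores, index=genotypes.sample_ids,
                               name=f"grs_{trait}"),
                     trait=trait, n_variants_used=len(present),
                     call_rate=call_rate, missing_mode=missing)


def variance_explained(grs, trait_z, age, sex) -> VarianceExplained:
    """Incremental R² of the trait on the GRS, adjusted for age and sex.

    Computes R²(trait ~ GRS + age + sex) − R²(trait ~ age + sex) on rows
    complete for all four variables, and the GRS slope with its SE (trait in
    SD units per risk allele).
    """
    import statsmodels.api as sm

    scores = grs.scores if isinstance(grs, GRSResult) else pd.Series(grs)
    df = pd.DataFrame({
        "trait": np.asarray(trait_z, dtype=float),
        "grs": scores.to_numpy(dtype=float),
        "age": np.asarray(age, dtype=float),
        "sex": np.asarray(sex, dtype=float),
    }).dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 complete samples")
    if df["grs"].std() == 0:
        raise ValueError("zero GRS variance")
    base = sm.OLS(df["trait"], sm.add_constant(df[["age", "sex"]])).fit()
    full = sm.OLS(df["trait"], sm.add_constant(df[["grs", "age", "sex"]])).fit()
    return VarianceExplained(
        r2=float(full.rsquared - base.rsquared),
        beta=float(full.params["grs"]),
        se=float(full.bse["grs"]),
        n=int(len(df)))
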