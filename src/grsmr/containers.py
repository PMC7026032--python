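"""Core in-memory containers shared by the simulator and the analysis stages.

A :class:`GenotypeMatrix` holds effect-allele dosages (0/1/2, ``NaN`` for
missing) for samples × variants together with per-variant allele metadata; an
:class:`InstrumentSet` holds the variant → effect-allele → trait definitions a
genetic risk score is built from.  Cohort phenotypes travel as a plain
:class:`pandas.DataFrame` with the documented column set (see
:mod:`grsmr.simulate`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "InstrumentSet", "TRAITS"]

#: Canonical trait labels, in the order panels are defined.
TRAITS = ("neuroticism", "education", "activity")

_VARIANT_COLS = ["variant_id", "effect_allele", "other_allele", "eaf", "trait"]


@dataclass
class GenotypeMatrix:
    """Samples × variants effect-allele dosage matrix with variant metadata.

    Parameters
    ----------
    dosages
        DataFrame indexed by sample id, one column per variant id, values in
        {0, 1, 2} with ``NaN`` for missing calls.  Dosages count copies of the
        variant's effect allele.
    variants
        DataFrame indexed by variant id with columns ``effect_allele``,
        ``other_allele``, ``eaf`` (effect-allele frequency) and ``trait``.
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.variants = self.variants.copy()
        if "variant_id" in self.variants.columns:
            self.variants = self.variants.set_index("variant_id")
        missing = [c for c in ("effect_allele", "other_allele", "eaf", "trait")
                   if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table lacks columns: {missing}")
        if not self.variants.index.is_unique:
            dup = self.variants.index[self.variants.index.duplicated()].unique()
            raise ValueError(f"duplicated variant ids: {list(dup)[:5]}")
        if list(self.dosages.columns) != list(self.variants.index):
            if set(self.dosages.columns) != set(self.variants.index):
                raise ValueError("dosage columns and variant table disagree")
            self.variants = self.variants.loc[self.dosages.columns]
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        self.dosages.columns.name = None
        self.dosages.index.name = "sample_id"

    # -- basic views ---------------------------------------------------

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def variant_ids(self) -> pd.Index:
        return self.dosages.columns

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def call_rate(self) -> pd.Series:
        """Fraction of non-missing calls per variant."""
        return self.dosages.notna().mean(axis=0)

    def empirical_eaf(self) -> pd.Series:
        """In-sample effect-allele frequency (mean dosage / 2)."""
        return self.dosages.mean(axis=0, skipna=True) / 2.0

    def subset(self, variant_ids) -> "GenotypeMatrix":
        ids = [v for v in variant_ids if v in self.dosages.columns]
        return GenotypeMatrix(self.dosages[ids], self.variants.loc[ids])

    # -- text serialisation -------------------------------------------

    def to_tsv(self, dosage_path, variant_path) -> None:
        """Write the dosage matrix and the variant side-car as TSV.

        The dosage file has a header ``sample_id`` + variant ids; missing
        dosages are encoded ``NA``.
        """
        out = self.dosages.copy()
        out.index.name = "sample_id"
        out.to_csv(dosage_path, sep="\t", na_rep="NA", float_format="%g")
        var = self.variants.reset_index()
        var.columns = _VARIANT_COLS
        var.to_csv(variant_path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, dosage_path, variant_path) -> "GenotypeMatrix":
        dos = pd.read_csv(dosage_path, sep="\t", index_col="sample_id",
                          na_values=["NA"]).astype(float)
        var = pd.read_csv(variant_path, sep="\t")
        return cls(dos, var)

    def to_vcf(self, path) -> None:
        """Write a minimal VCF 4.2 with GT genotypes on one synthetic contig.

        The effect allele is written as REF, so GT allele counts relative to
        ALT encode the *other* allele; readers must re-orient using the
        variant side-car (exercised by :func:`grsmr.grs.read_genotypes`).
        Missing dosages become ``./.``; heterozygotes ``0/1``.
        """
        samples = [str(s) for s in self.sample_ids]
        buf = io.StringIO()
        buf.write("##fileformat=VCFv4.2\n")
        buf.write("##contig=<ID=1>\n")
        buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                  + "\t".join(samples) + "\n")
        gt_for = {0.0: "1/1", 1.0: "0/1", 2.0: "0/0"}
        arr = self.dosages.to_numpy(dtype=float)
        for j, vid in enumerate(self.variant_ids):
            rec = self.variants.loc[vid]
            cells = ["./." if np.isnan(d) else gt_for[d] for d in arr[:, j]]
            buf.write(f"1\t{j + 1}\t{vid}\t{rec.effect_allele}\t"
                      f"{rec.other_allele}\t.\tPASS\t.\tGT\t"
                      + "\t".join(cells) + "\n")
        Path(path).write_text(buf.getvalue())


@dataclass
class InstrumentSet:
    """Variant → effect-allele → trait definitions for GRS construction."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        req = ["variant_id", "effect_allele", "other_allele", "trait"]
        missing = [c for c in req if c not in self.table.columns]
        if missing:
            raise ValueError(f"instrument table lacks columns: {missing}")
        for col in ("effect_allele", "other_allele"):
            bad = ~self.table[col].isin(list("ACGT"))
            if bad.any():
                raise ValueError(f"non-ACGT allele in column {col}")
        dup = self.table.duplicated(subset=["variant_id", "trait"])
        if dup.any():
            raise ValueError("duplicated variant id within a trait panel")

    def for_trait(self, trait: str) -> pd.DataFrame:
        sub = self.table[self.table["trait"] == trait]
        if sub.empty:
            raise KeyError(f"no instruments for trait {trait!r}")
        return sub.reset_index(drop=True)

    @property
    def traits(self) -> list[str]:
        return list(dict.fromkeys(self.table["trait"]))

    def panel_sizes(self) -> pd.Series:
        return self.table.groupby("trait", sort=False).size()

    def to_tsv(self, path) -> None:
        cols = ["variant_id", "effect_allele", "other_allele", "trait"]
        self.table[cols].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "InstrumentSet":
        return cls(pd.read_csv(path, sep="\t"))

    @classmethod
    def from_genotypes(cls, genotypes: GenotypeMatrix) -> "InstrumentSet":
        """Build the instrument table directly from simulated variant metadata."""
        tab = genotypes.variants.reset_index()
        tab = tab.rename(columns={tab.columns[0]: "variant_id"})
        return cls(tab[["variant_id", "effect_allele", "other_allele", "trait"]])
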