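"""End-to-end orchestration: simulate/load → derive → GRS → observational →
MR → MVMR → screening → sensitivity re-fit → power → report.

Every stage writes a plain TSV whose first line is a versioned header
comment carrying the run's config hash, so any stage can be re-run and
cross-checked in isolation; :func:`make_report` refuses to assemble outputs
with mismatched hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .causal import ModelSpec, fit_mvmr, fit_ols, fit_tsls
from .config import RunConfig
from .containers import TRAITS, GenotypeMatrix, InstrumentSet
from .grs import align_effect_alleles, compute_unweighted_grs, variance_explained, variant_qc
from .phenotypes import derive_phenotypes
from .power import PowerQuery, mr_ncp, mr_power
from .screening import TRAIT_Z_COLUMN, build_sensitivity_grs, screen_instruments
from .simulate import read_cohort, simulate_cohort, write_cohort

__all__ = ["run_pipeline", "make_report", "StageError"]

log = logging.getLogger("grsmr")

_MODELS = ("observational_univariable", "observational_multivariable",
           "mr_univariable", "mvmr")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _config_hash(config: RunConfig) -> str:
    import dataclasses
    d = dataclasses.asdict(config)
    d.pop("out_dir", None)  # scientific config only: relocatable runs
    blob = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# grsmr-table v1 config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", na_rep="NA", index=index)


def read_stage_tsv(path) -> tuple[pd.DataFrame, str]:
    """Read a stage TSV, returning the table and its config hash."""
    with open(path) as fh:
        header = fh.readline().strip()
    cfg = header.split("config=")[-1] if "config=" in header else ""
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"]), cfg


def _result_rows(model: str, res, trait_of: dict) -> list[dict]:
    rows = []
    for exp, trait in trait_of.items():
        if exp not in set(res.table["term"]):
            continue
        t = res.term(exp)
        fsf = res.first_stage_f.get(exp) if res.first_stage_f is not None else np.nan
        swf = res.conditional_f.get(exp) if res.conditional_f is not None else np.nan
        rows.append({
            "model": model, "trait": trait, "term": exp,
            "estimate": t["estimate"], "se": t["se"],
            "ci_low": t["ci_low"], "ci_high": t["ci_high"], "p": t["p"],
            "n": int(t["n"]), "first_stage_f": fsf, "sw_conditional_f": swf,
        })
    return rows


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages in order; returns the run directory.

    Any stage failure raises :class:`StageError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = _config_hash(config)
    stage = "setup"
    try:
        stage = "inputs"
        if config.simulation is not None:
            sim = config.simulation.replace(seed=config.seed)
            genotypes, cohort, instruments = simulate_cohort(sim)
            genotypes.to_tsv(out / "genotypes.tsv", out / "variants.tsv")
            genotypes.to_vcf(out / "genotypes.vcf")
            write_cohort(cohort, out / "cohort.tsv")
            instruments.to_tsv(out / "instruments.tsv")
        else:
            genotypes = GenotypeMatrix.from_tsv(config.genotypes_path,
                                                config.variants_path)
            cohort = read_cohort(config.cohort_path)
            instruments = (InstrumentSet.from_tsv(config.instruments_path)
                           if config.instruments_path
                           else InstrumentSet.from_genotypes(genotypes))
        log.info("inputs: %d samples, %d variants",
                 genotypes.n_samples, genotypes.n_variants)

        stage = "derive"
        derived = derive_phenotypes(cohort)
        _write_tsv(derived.attrition, out / "attrition.tsv", cfg_hash)
        _write_tsv(derived.table, out / "derived.tsv", cfg_hash, index=True)
        log.info("derive: %d of %d samples eligible",
                 derived.n_eligible, len(cohort))
        for _, row in derived.attrition.iterrows():
            log.info("  exclusion %-20s removed %6d remaining %7d",
                     row["criterion"], row["n_removed"], row["n_remaining"])

        stage = "grs"
        genotypes, qc_log = variant_qc(genotypes)
        if len(qc_log):
            log.info("grs: %d variant(s) removed by call-rate QC", len(qc_log))
        genotypes = align_effect_alleles(genotypes, instruments)
        data = derived.table.copy()
        grs_summary = []
        for trait in TRAITS:
            res = compute_unweighted_grs(genotypes, instruments, trait)
            data[f"grs_{trait}"] = res.scores
            elig = data["analysis_eligible"].astype(bool)
            ve = variance_explained(
                res.scores[elig], data.loc[elig, TRAIT_Z_COLUMN[trait]],
                data.loc[elig, "age"], data.loc[elig, "sex"])
            grs_summary.append({
                "trait": trait, "n_variants": res.n_variants_used,
                "beta": ve.beta, "se": ve.se,
                "variance_explained_pct": 100.0 * ve.r2, "n": ve.n})
        grs_summary = pd.DataFrame(grs_summary)
        _write_tsv(grs_summary, out / "grs_summary.tsv", cfg_hash)
        _write_tsv(data[[f"grs_{t}" for t in TRAITS]],
                   out / "grs.tsv", cfg_hash, index=True)

        covs = ["age", "sex", "centre", "tdi"]
        if config.adjust_bmi:
            covs.append("log_bmi")
        trait_of = {TRAIT_Z_COLUMN[t]: t for t in TRAITS}
        exposures = list(trait_of)
        instruments_cols = [f"grs_{t}" for t in TRAITS]
        rows = []

        stage = "observational"
        for exp in exposures:
            res = fit_ols(ModelSpec("job_satisfaction", (exp,),
                                    covariates=tuple(covs)), data)
            rows += _result_rows("observational_univariable", res, trait_of)
        res = fit_ols(ModelSpec("job_satisfaction", tuple(exposures),
                                covariates=tuple(covs)), data)
        rows += _result_rows("observational_multivariable", res, trait_of)

        stage = "mr"
        for exp, g in zip(exposures, instruments_cols):
            res = fit_tsls(ModelSpec("job_satisfaction", (exp,), (g,),
                                     tuple(covs), "tsls"), data)
            rows += _result_rows("mr_univariable", res, trait_of)

        stage = "mvmr"
        res = fit_mvmr(ModelSpec("job_satisfaction", tuple(exposures),
                                 tuple(instruments_cols), tuple(covs),
                                 "mvmr"), data)
        rows += _result_rows("mvmr", res, trait_of)
        results = pd.DataFrame(rows)
        _write_tsv(results, out / "results.tsv", cfg_hash)

        stage = "screening"
        if config.screening:
            screening = screen_instruments(genotypes, data, instruments)
            _write_tsv(screening, out / "screening.tsv", cfg_hash)
            sens = build_sensitivity_grs(screening, genotypes, instruments)
            sens_rows = []
            for trait, gres in sens.items():
                data[f"grs_sens_{trait}"] = gres.scores
                excluded = int((screening["trait"] == trait).sum()
                               - gres.n_variants_used)
                log.info("screening %-12s retained %3d excluded %3d",
                         trait, gres.n_variants_used, excluded)
            for exp, trait in trait_of.items():
                res = fit_tsls(ModelSpec(
                    "job_satisfaction", (exp,), (f"grs_sens_{trait}",),
                    tuple(covs), "tsls"), data)
                sens_rows += _result_rows("mr_univariable_sensitivity", res,
                                          trait_of)
            res = fit_mvmr(ModelSpec(
                "job_satisfaction", tuple(exposures),
                tuple(f"grs_sens_{t}" for t in TRAITS), tuple(covs),
                "mvmr"), data)
            sens_rows += _result_rows("mvmr_sensitivity", res, trait_of)
            sens_tab = pd.DataFrame(sens_rows)
            counts = screening.groupby("trait")["retained"].agg(
                retained="sum", total="count").reset_index()
            _write_tsv(counts, out / "screening_counts.tsv", cfg_hash)
            _write_tsv(sens_tab, out / "sensitivity.tsv", cfg_hash)

        stage = "power"
        n_outcome = int(data.loc[data["analysis_eligible"].astype(bool),
                                 "job_satisfaction"].notna().sum())
        power_rows = []
        for _, row in grs_summary.iterrows():
            r2 = max(row["variance_explained_pct"] / 100.0, 1e-8)
            q = PowerQuery(max(n_outcome, 2), r2, config.power_beta,
                           config.alpha)
            power_rows.append({
                "trait": row["trait"], "n": q.n, "r2_gx": r2,
                "beta_std": q.beta_std, "alpha": q.alpha,
                "ncp": mr_ncp(q), "power": mr_power(q),
                "power_pct": round(100.0 * mr_power(q))})
        _write_tsv(pd.DataFrame(power_rows), out / "power.tsv", cfg_hash)

        stage = "manifest"
        manifest = {
            "package": "grsmr", "version": __version__,
            "config_hash": cfg_hash, "seed": config.seed,
            "n_samples": int(genotypes.n_samples),
            "n_variants": int(genotypes.n_variants),
            "n_eligible": int(derived.n_eligible),
            "n_outcome": n_outcome,
            "covariates": covs, "adjust_bmi": bool(config.adjust_bmi),
            "screening": bool(config.screening),
            "numpy": np.__version__, "pandas": pd.__version__,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

        stage = "report"
        make_report(out)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise StageError(stage, exc) from exc
    return out


def make_report(run_dir) -> str:
    """Render the plain-text results report for a completed run.

    One row per (trait × model); weak instruments (first-stage F < 10) are
    flagged; screening and power sections included.  Raises if stage
    outputs are missing or carry mismatched config hashes.
    """
    run_dir = Path(run_dir)
    manifest = json.loads((run_dir / "manifest.json").read_text())
    results, h1 = read_stage_tsv(run_dir / "results.tsv")
    power, h2 = read_stage_tsv(run_dir / "power.tsv")
    hashes = {h1, h2}

    lines = []
    lines.append("grsmr analysis report")
    lines.append("=" * 70)
    lines.append(f"config {manifest['config_hash']}  seed {manifest['seed']}  "
                 f"n={manifest['n_samples']}  eligible={manifest['n_eligible']}  "
                 f"with outcome={manifest['n_outcome']}")
    lines.append("")
    lines.append(f"{'model':28s}{'trait':14s}{'estimate (95% CI)':28s}"
                 f"{'p':>10s}{'F':>8s}{'S-W F':>8s}")
    lines.append("-" * 96)
    for _, r in results.iterrows():
        est = f"{r['estimate']: .3f} ({r['ci_low']: .3f} to {r['ci_high']: .3f})"
        f = "" if pd.isna(r["first_stage_f"]) else f"{r['first_stage_f']:.1f}"
        swf = "" if pd.isna(r["sw_conditional_f"]) else f"{r['sw_conditional_f']:.1f}"
        weak = ""
        if not pd.isna(r["first_stage_f"]) and r["first_stage_f"] < 10:
            weak = "  ** WEAK INSTRUMENT (F < 10)"
        lines.append(f"{r['model']:28s}{r['trait']:14s}{est:28s}"
                     f"{r['p']:10.2e}{f:>8s}{swf:>8s}{weak}")
    lines.append("")

    lines.append("Instrument screening")
    cpath = run_dir / "screening_counts.tsv"
    if cpath.exists():
        counts, h3 = read_stage_tsv(cpath)
        hashes.add(h3)
        for _, r in counts.iterrows():
            lines.append(f"  {r['trait']:14s} retained {int(r['retained']):4d}"
                         f" of {int(r['total']):4d}")
        spath = run_dir / "sensitivity.tsv"
        if spath.exists():
            sens, h4 = read_stage_tsv(spath)
            hashes.add(h4)
            lines.append("  sensitivity-GRS re-fit:")
            for _, r in sens.iterrows():
                lines.append(
                    f"  {r['model']:28s}{r['trait']:14s}"
                    f"{r['estimate']: .3f} ({r['ci_low']: .3f} to "
                    f"{r['ci_high']: .3f})  p={r['p']:.2e}")
    else:
        lines.append("  skipped")
    lines.append("")

    lines.append("Analytic power (per-trait instrument R², "
                 f"beta_std={power['beta_std'].iloc[0]:g})")
    for _, r in power.iterrows():
        lines.append(f"  {r['trait']:14s} n={int(r['n']):7d}  "
                     f"R²={100 * r['r2_gx']:.2f}%  NCP={r['ncp']:8.2f}  "
                     f"power={int(r['power_pct'])}%")
    if len(hashes) > 1:
        raise ValueError(f"config-hash mismatch across stage outputs: {hashes}")
    text = "\n".join(lines) + "\n"
    (run_dir / "report.txt").write_text(text)
    return text
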