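"""Synthetic biobank-style cohort generator.

Generates, under one global seed, everything the downstream analysis needs:
biallelic SNP genotypes in Hardy–Weinberg equilibrium partitioned into three
trait panels, three correlated exposures whose population R² on their own
unweighted genetic risk score matches a configurable preset, an unmeasured
confounder, optional pleiotropic (invalid) instruments with direct outcome
effects, questionnaire-style raw phenotype fields (neuroticism 0–12, highest
qualification, weekly activity days/durations), the covariates age, sex,
assessment centre, Townsend deprivation index and BMI, cohort-exclusion
flags, and a job-satisfaction outcome observed only for employed samples.

The structural model
--------------------
For trait *j* with standardised GRS :math:`S_j`, confounder :math:`U` and
shared latent factors :math:`F` with correlation matrix *R*:

.. math::
    X_j = \\sqrt{r^2_j}\\,S_j + c_j U + \\sqrt{1 - r^2_j - c_j^2}\\,F_j

so each exposure has unit population variance and population R² on its GRS
equal to ``target_r2[j]``.  Each latent exposure is mapped monotonically to
its questionnaire-style observed field (neuroticism 0–12, qualification
category, activity days/durations), and the latent outcome acts on the
*standardised observed* exposures :math:`\\tilde X_j` — the analysis scale —
so ``true_effects`` is exactly the estimand the MR stages target:

.. math::
    Y = \\sum_j \\beta_j \\tilde X_j + c_y U + \\sum_{v\\ \\mathrm{invalid}}
        \\delta (d_v - 2p_v) + \\gamma' W + \\varepsilon

with small covariate effects :math:`\\gamma` and residual scaled so the
latent outcome has unit variance by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import FLAG_ORDER, SimulationConfig
from .containers import TRAITS, GenotypeMatrix, InstrumentSet

__all__ = [
    "simulate_genotypes",
    "simulate_exposures",
    "simulate_outcome",
    "simulate_covariates_and_flags",
    "simulate_cohort",
    "QUALIFICATION_LEVELS",
    "COHORT_COLUMNS",
]

#: Qualification categories from lowest to highest attainment.
QUALIFICATION_LEVELS = ("none", "cse_gcse", "a_level", "nvq_hnd",
                        "other_professional", "degree")
_QUAL_PROBS = (0.17, 0.26, 0.12, 0.22, 0.05, 0.18)

#: Fixed column order of the written cohort table.
COHORT_COLUMNS = [
    "age", "sex", "centre", "tdi", "bmi", "employed",
    "neuroticism", "qualification",
    "walk_days", "walk_min", "mod_days", "mod_min", "vig_days", "vig_min",
    "job_satisfaction",
    *FLAG_ORDER,
    "u_confounder", "latent_neuroticism", "latent_education",
    "latent_activity", "latent_outcome",
]

# Marginal class probabilities for the likert job-satisfaction mapping
# (skewed towards satisfied, as satisfaction scales typically are).
_LIKERT_PROBS = (0.02, 0.04, 0.09, 0.25, 0.40, 0.20)

# MET split across activity types and IPAQ coefficients.
_MET_SHARES = {"walk": 0.4, "mod": 0.4, "vig": 0.2}
_MET_COEF = {"walk": 3.3, "mod": 4.0, "vig": 8.0}


def _binom_pmf(n: int, p: float) -> np.ndarray:
    from scipy.stats import binom
    return binom.pmf(np.arange(n + 1), n, p)


def _quantile_cutpoints(probs) -> np.ndarray:
    """Standard-normal cut-points for fixed class probabilities."""
    from scipy.stats import norm
    cum = np.cumsum(probs)[:-1]
    return norm.ppf(cum / np.sum(probs))


def _attenuation_discrete(probs, values) -> float:
    """corr(f(Z), Z) for Z ~ N(0,1) quantile-binned into classes with the
    given probabilities and assigned values (closed form via the truncated
    normal first moment)."""
    from scipy.stats import norm
    probs = np.asarray(probs, dtype=float)
    values = np.asarray(values, dtype=float)
    phi = norm.pdf(norm.ppf(np.cumsum(probs)[:-1] / probs.sum()))
    lower = np.concatenate([[0.0], phi])
    upper = np.concatenate([phi, [0.0]])
    cov = float(values @ (lower - upper))
    mean = float(probs @ values)
    var = float(probs @ values**2) - mean**2
    return cov / np.sqrt(var)


def _attenuation_met(mu: float = 7.2, sigma: float = 1.0,
                     shift: float = 30.0) -> float:
    """corr(log1p(MET(Z)), Z) for the log-normal MET mapping, by
    Gauss-Hermite quadrature."""
    x, w = np.polynomial.hermite_e.hermegauss(201)
    w = w / np.sqrt(2.0 * np.pi)
    vals = np.log1p(np.maximum(np.exp(mu + sigma * x) - shift, 0.0))
    mean = float(w @ vals)
    var = float(w @ vals**2) - mean**2
    cov = float(w @ (vals * x))
    return cov / np.sqrt(var)


def _trait_slices(config: SimulationConfig) -> dict[str, slice]:
    out, start = {}, 0
    for trait, m in zip(TRAITS, config.n_variants_per_trait):
        out[trait] = slice(start, start + m)
        start += m
    return out


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw HWE genotypes for all three trait panels.

    Per variant, an effect-allele frequency is drawn uniformly from
    ``maf_range`` and dosages from Binomial(2, eaf); missing calls are
    applied completely at random at ``missing_genotype_rate``.  Alleles are
    assigned avoiding ambiguous-strand (A/T, C/G) pairs.
    """
    rng = config.rng("genotypes")
    n = config.n_samples
    total = sum(config.n_variants_per_trait)
    eaf = rng.uniform(*config.maf_range, size=total)
    dosages = rng.binomial(2, eaf[None, :], size=(n, total)).astype(float)
    if config.missing_genotype_rate > 0:
        mask = rng.random(size=dosages.shape) < config.missing_genotype_rate
        dosages[mask] = np.nan

    # unambiguous allele pairs only (strand flips are undetectable for A/T, C/G)
    pairs = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
    pick = rng.integers(0, len(pairs), size=total)
    swap = rng.random(total) < 0.5

    records, ids = [], []
    slices = _trait_slices(config)
    for trait in TRAITS:
        sl = slices[trait]
        for k in range(sl.start, sl.stop):
            a, b = pairs[pick[k]]
            ea, oa = (b, a) if swap[k] else (a, b)
            vid = f"rs{trait[:3]}{k - sl.start + 1:04d}"
            ids.append(vid)
            records.append((vid, ea, oa, float(eaf[k]), trait))
    variants = pd.DataFrame(
        records, columns=["variant_id", "effect_allele", "other_allele",
                          "eaf", "trait"])
    sample_ids = pd.Index([f"S{i + 1:07d}" for i in range(n)], name="sample_id")
    dos = pd.DataFrame(dosages, index=sample_ids, columns=ids)
    return GenotypeMatrix(dos, variants)


def _imputed_dosages(genotypes: GenotypeMatrix) -> np.ndarray:
    """Dosage array with missing calls replaced by 2·EAF (declared frequency)."""
    d = genotypes.dosages.to_numpy(dtype=float, copy=True)
    if np.isnan(d).any():
        fill = 2.0 * genotypes.variants["eaf"].to_numpy(dtype=float)
        idx = np.where(np.isnan(d))
        d[idx] = fill[idx[1]]
    return d


def _standardised_grs(genotypes: GenotypeMatrix, config: SimulationConfig
                      ) -> np.ndarray:
    """Population-standardised unweighted GRS per trait, columns in TRAITS order."""
    d = _imputed_dosages(genotypes)
    trait_lab = genotypes.variants["trait"].to_numpy()
    eaf = genotypes.variants["eaf"].to_numpy(dtype=float)
    out = np.empty((genotypes.n_samples, 3))
    for j, trait in enumerate(TRAITS):
        cols = trait_lab == trait
        p = eaf[cols]
        score = d[:, cols].sum(axis=1)
        mu = 2.0 * p.sum()
        sd = np.sqrt((2.0 * p * (1.0 - p)).sum())
        out[:, j] = (score - mu) / sd
    return out


def simulate_exposures(genotypes: GenotypeMatrix, config: SimulationConfig
                       ) -> pd.DataFrame:
    """Latent exposures plus their questionnaire-style observed fields.

    Returns a frame indexed like the genotypes with the latent exposures and
    confounder, the neuroticism raw score (monotone quantile binning of the
    latent trait onto 0–12), the highest-qualification category, and weekly
    walking/moderate/vigorous days and durations reproducing a log-normal
    MET distribution.
    """
    rng = config.rng("exposures")
    n = genotypes.n_samples
    S = _standardised_grs(genotypes, config)

    R = config.correlation_matrix
    L = np.linalg.cholesky(R + 1e-12 * np.eye(3))
    F = rng.standard_normal((n, 3)) @ L.T
    U = rng.standard_normal(n)

    # target_r2 is the analysis-scale (observed z-score) R2; the monotone
    # discretisations attenuate latent-observed correlation, so the latent
    # GRS share is inflated by the closed-form attenuation factor per trait.
    from .phenotypes import DEFAULT_EDUCATION_MAPPING
    attn = np.array([
        _attenuation_discrete(_binom_pmf(12, 0.35), np.arange(13)),
        _attenuation_discrete(
            _QUAL_PROBS,
            [DEFAULT_EDUCATION_MAPPING[q] for q in QUALIFICATION_LEVELS]),
        _attenuation_met(),
    ])
    r2 = np.asarray(config.target_r2) / attn**2
    c = np.asarray(config.confounder_exposures)
    if np.any(r2 + c**2 >= 1.0):
        raise ValueError("target_r2 infeasible after discretisation "
                         "attenuation given the confounder loadings")
    lam = np.sqrt(1.0 - r2 - c**2)
    X = np.sqrt(r2)[None, :] * S + c[None, :] * U[:, None] + lam[None, :] * F

    out = pd.DataFrame(index=genotypes.sample_ids)
    out["u_confounder"] = U
    out["latent_neuroticism"] = X[:, 0]
    out["latent_education"] = X[:, 1]
    out["latent_activity"] = X[:, 2]

    # neuroticism 0-12: monotone quantile binning with an EPQ-N-like marginal
    cuts = _quantile_cutpoints(_binom_pmf(12, 0.35))
    out["neuroticism"] = np.searchsorted(cuts, X[:, 0]).astype(int)

    # highest qualification: six ordered categories
    qcuts = _quantile_cutpoints(_QUAL_PROBS)
    qidx = np.searchsorted(qcuts, X[:, 1])
    out["qualification"] = pd.Categorical.from_codes(
        qidx, categories=list(QUALIFICATION_LEVELS), ordered=True)

    # physical activity: log-normal weekly MET, decomposed into days/minutes
    met = np.maximum(np.exp(7.2 + 1.0 * X[:, 2]) - 30.0, 0.0)
    active = met > 0
    for kind in ("walk", "mod", "vig"):
        days = np.zeros(n, dtype=int)
        days[active] = rng.integers(1, 8, size=int(active.sum()))
        minutes = np.zeros(n)
        with np.errstate(divide="ignore", invalid="ignore"):
            minutes[active] = (_MET_SHARES[kind] * met[active]
                               / (_MET_COEF[kind] * days[active]))
        out[f"{kind}_days"] = days
        out[f"{kind}_min"] = np.round(minutes, 1)
    return out


def simulate_covariates_and_flags(config: SimulationConfig) -> pd.DataFrame:
    """Covariates, employment status and the six cohort-exclusion flags.

    Age is uniform on [37, 73] years, sex Bernoulli(0.53) (1 = female),
    centre one of ten categorical labels, TDI Gumbel-shaped (right-skewed,
    mean ≈ −1.3), BMI log-normal around 27 kg/m²; each exclusion flag is an
    independent Bernoulli at its configured rate.
    """
    rng = config.rng("covariates")
    n = config.n_samples
    idx = pd.Index([f"S{i + 1:07d}" for i in range(n)], name="sample_id")
    cov = pd.DataFrame(index=idx)
    cov["age"] = np.round(rng.uniform(37.0, 73.0, size=n), 1)
    cov["sex"] = (rng.random(n) < 0.53).astype(int)
    centre_probs = np.array([0.16, 0.14, 0.13, 0.11, 0.10, 0.09, 0.08,
                             0.07, 0.06, 0.06])
    labels = [f"centre_{i + 1:02d}" for i in range(10)]
    cov["centre"] = pd.Categorical.from_codes(
        rng.choice(10, size=n, p=centre_probs), categories=labels)
    cov["tdi"] = np.round(rng.gumbel(-2.6, 2.3, size=n), 3)
    cov["bmi"] = np.round(np.exp(rng.normal(np.log(27.0), 0.15, size=n)), 2)
    cov["employed"] = (rng.random(n) < config.employment_rate).astype(int)
    for flag in FLAG_ORDER:
        cov[flag] = rng.random(n) < config.flag_rates[flag]
    return cov


def simulate_outcome(cohort: pd.DataFrame, genotypes: GenotypeMatrix,
                     config: SimulationConfig) -> pd.DataFrame:
    """Append the latent and observed job-satisfaction outcome.

    Requires the exposure and covariate columns to be present.  The latent
    outcome combines the causal exposure effects, the confounder, direct
    effects of the first ``n_invalid`` variants of each panel (pleiotropy)
    and Gaussian noise; under ``outcome_scale='likert6'`` it is mapped
    monotonically onto {1..6} by quantile cut-points.  Unemployed samples
    get a missing outcome.
    """
    needed = ["neuroticism", "qualification", "walk_days", "u_confounder",
              "employed", "age", "sex", "tdi"]
    missing = [c for c in needed if c not in cohort.columns]
    if missing:
        raise ValueError(f"outcome requested before columns exist: {missing}")
    from .phenotypes import compute_met_score, map_education_years, standardize

    rng = config.rng("outcome")
    n = len(cohort)
    # Causal effects act on the analysis-scale exposures: the standardised
    # observed scores (neuroticism 0-12, education leaving age, log MET),
    # so `true_effects` is exactly the estimand the MR stages target
    # (outcome units per 1 SD of the measured exposure).
    met = compute_met_score(
        cohort["walk_days"], cohort["walk_min"], cohort["mod_days"],
        cohort["mod_min"], cohort["vig_days"], cohort["vig_min"])
    edu_years = map_education_years(cohort["qualification"])
    X = np.column_stack([
        standardize(cohort["neuroticism"].to_numpy(dtype=float)),
        standardize(edu_years),
        standardize(np.log1p(met)),
    ])
    beta = np.asarray(config.true_effects)
    cy = float(config.confounder_outcome)

    y = X @ beta + cy * cohort["u_confounder"].to_numpy()
    y = (y + config.beta_age * (cohort["age"].to_numpy() - 55.0)
         + config.beta_sex * cohort["sex"].to_numpy()
         + config.beta_tdi * cohort["tdi"].to_numpy())

    # direct (pleiotropic) variant effects, centred dosages
    pleio_var = 0.0
    d = _imputed_dosages(genotypes)
    eaf = genotypes.variants["eaf"].to_numpy(dtype=float)
    trait_lab = genotypes.variants["trait"].to_numpy()
    delta = float(config.invalid_effect)
    for trait, k in zip(TRAITS, config.n_invalid):
        if k == 0:
            continue
        cols = np.where(trait_lab == trait)[0][:k]
        centred = d[:, cols] - 2.0 * eaf[cols][None, :]
        y = y + delta * centred.sum(axis=1)
        pleio_var += (delta**2 * 2.0 * eaf[cols] * (1.0 - eaf[cols])).sum()

    if config.outcome_noise_sd is not None:
        noise_sd = float(config.outcome_noise_sd)
    else:  # unit total latent variance, floored so noise never vanishes
        noise_sd = np.sqrt(max(1.0 - float(np.var(y)), 0.25))
    y = y + noise_sd * rng.standard_normal(n)

    out = cohort.copy()
    out["latent_outcome"] = y
    if config.outcome_scale == "likert6":
        cuts = np.quantile(y, np.cumsum(_LIKERT_PROBS)[:-1])
        js = (np.searchsorted(cuts, y) + 1).astype(float)
    else:
        js = y.copy()
    js[out["employed"].to_numpy() == 0] = np.nan
    out["job_satisfaction"] = js
    return out


def simulate_cohort(config: SimulationConfig
                    ) -> tuple[GenotypeMatrix, pd.DataFrame, InstrumentSet]:
    """Run the full generator: genotypes, covariates, exposures, outcome.

    Returns the genotype matrix (with missingness applied), the cohort table
    in the documented column order, and the matching instrument set.
    """
    genotypes = simulate_genotypes(config)
    cov = simulate_covariates_and_flags(config)
    exp = simulate_exposures(genotypes, config)
    cohort = cov.join(exp)
    cohort = simulate_outcome(cohort, genotypes, config)
    cohort = cohort[COHORT_COLUMNS]
    return genotypes, cohort, InstrumentSet.from_genotypes(genotypes)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write the cohort table as TSV with ``NA`` for missing values."""
    cohort.to_csv(path, sep="\t", na_rep="NA")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA"])
    for flag in FLAG_ORDER:
        if flag in df.columns:
            df[flag] = df[flag].astype(bool)
    return df
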