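"""Run and simulation configuration objects with YAML round-tripping.

:class:`SimulationConfig` collects every generative parameter of the synthetic
cohort: panel sizes, allele-frequency range, the per-trait fraction of
exposure variance explained by its genetic risk score, causal effects on the
outcome, exposure correlation, confounding loadings, pleiotropy, genotype
missingness, cohort-exclusion flag rates and the outcome scale.  Defaults
emulate the biobank study the generator is modelled on: three exposures
(neuroticism, education, physical activity) whose unweighted risk scores
explain 1.14%, 0.63% and 0.03% of trait variance, a 1–6 job-satisfaction
outcome observed only for employed participants, and the standard covariate
set (age, sex, assessment centre, Townsend deprivation index, BMI).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .containers import TRAITS

__all__ = ["SimulationConfig", "RunConfig", "DEFAULT_FLAG_RATES", "FLAG_ORDER"]

#: Exclusion flags in the order the attrition cascade applies them.
FLAG_ORDER = (
    "consent_withdrawn",
    "sex_mismatch",
    "related",
    "non_british",
    "icd10_mental_neuro",
    "neuroticism_missing",
)

# Marginal flag probabilities emulating the source cohort's attrition
# fractions (counts removed per criterion over ~500k enrolled).
DEFAULT_FLAG_RATES = {
    "consent_withdrawn": 0.00017,
    "sex_mismatch": 0.00075,
    "related": 0.0346,
    "non_british": 0.1125,
    "icd10_mental_neuro": 0.0512,
    "neuroticism_missing": 0.1446,
}


def _as_tuple3(x, name: str, dtype=float) -> tuple:
    x = tuple(dtype(v) for v in np.atleast_1d(np.asarray(x)).ravel())
    if len(x) == 1:
        x = x * 3
    if len(x) != 3:
        raise ValueError(f"{name} must have 3 entries (one per trait)")
    return x


@dataclass
class SimulationConfig:
    """Generative parameters for the synthetic cohort.

    Attributes
    ----------
    n_samples
        Cohort size before any exclusion.
    n_variants_per_trait
        Panel sizes for the neuroticism / education / physical-activity
        instruments (defaults are the post-QC panel sizes 136, 70, 22).
    maf_range
        Effect-allele frequencies are drawn uniformly from this interval,
        which must lie within (0, 0.5].
    target_r2
        Per-trait population R² of the exposure on its own unweighted GRS
        (defaults 0.0114, 0.0063, 0.0003).
    true_effects
        Direct causal effect of each exposure on the latent outcome, in
        outcome units per 1 SD of exposure.
    exposure_correlation
        3×3 correlation of the shared latent (non-genetic) exposure factors.
        The realised exposure correlation additionally includes the product
        of the confounder loadings.
    confounder_exposures, confounder_outcome
        Loadings of a single unmeasured standard-normal confounder on each
        exposure and on the outcome.  The omitted-variable bias of the
        observational slope for exposure *j* is approximately
        ``confounder_exposures[j] * confounder_outcome``.
    n_invalid, invalid_effect
        Number of pleiotropic (invalid) variants per panel, and their direct
        per-allele effect on the outcome.  Invalid variants are the first
        ones of each panel.
    missing_genotype_rate
        Completely-at-random missing-call fraction applied to the emitted
        genotype matrix (exposures are generated from the complete dosages).
    flag_rates
        Marginal Bernoulli rate for each cohort-exclusion flag.
    employment_rate
        Probability a participant is employed; job satisfaction is missing
        for the unemployed.
    outcome_scale
        ``"latent"`` keeps the continuous outcome; ``"likert6"`` maps it
        monotonically onto {1..6} by fixed quantile cut-points (which
        attenuates regression coefficients multiplicatively).
    outcome_noise_sd
        Residual SD of the latent outcome; ``None`` solves for unit total
        latent variance (floored at 0.5).
    beta_age, beta_sex, beta_tdi
        Small direct covariate effects on the outcome, so covariate
        adjustment in the analysis stages is non-trivial.
    seed
        Global integer seed; per-component sub-streams are derived from it
        deterministically.
    """

    n_samples: int = 20_000
    n_variants_per_trait: tuple = (136, 70, 22)
    maf_range: tuple = (0.05, 0.5)
    target_r2: tuple = (0.0114, 0.0063, 0.0003)
    true_effects: tuple = (-0.31, 0.0, 0.0)
    exposure_correlation: tuple = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))
    confounder_exposures: tuple = (0.2, 0.2, 0.2)
    confounder_outcome: float = 0.3
    n_invalid: tuple = (0, 0, 0)
    invalid_effect: float = 0.05
    missing_genotype_rate: float = 0.0
    flag_rates: dict = field(default_factory=lambda: dict(DEFAULT_FLAG_RATES))
    employment_rate: float = 0.8
    outcome_scale: str = "latent"
    outcome_noise_sd: float | None = None
    beta_age: float = 0.004
    beta_sex: float = 0.05
    beta_tdi: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        self.n_samples = int(self.n_samples)
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        self.n_variants_per_trait = _as_tuple3(
            self.n_variants_per_trait, "n_variants_per_trait", int)
        self.maf_range = tuple(float(v) for v in self.maf_range)
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        self.target_r2 = _as_tuple3(self.target_r2, "target_r2")
        if any(not (0.0 <= r < 1.0) for r in self.target_r2):
            raise ValueError("target_r2 entries must be in [0, 1)")
        self.true_effects = _as_tuple3(self.true_effects, "true_effects")
        R = np.asarray(self.exposure_correlation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("exposure_correlation must be 3x3")
        if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("exposure_correlation must be a correlation matrix")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ValueError("exposure_correlation must be positive semi-definite")
        self.exposure_correlation = tuple(
            tuple(float(v) for v in row) for row in R)
        self.confounder_exposures = _as_tuple3(
            self.confounder_exposures, "confounder_exposures")
        for r2, c in zip(self.target_r2, self.confounder_exposures):
            if r2 + c * c >= 1.0:
                raise ValueError(
                    "target_r2 + confounder loading² must be < 1 per trait")
        self.n_invalid = _as_tuple3(self.n_invalid, "n_invalid", int)
        for k, m in zip(self.n_invalid, self.n_variants_per_trait):
            if not (0 <= k <= m):
                raise ValueError("n_invalid must be within [0, panel size]")
        if not (0.0 <= self.missing_genotype_rate < 1.0):
            raise ValueError("missing_genotype_rate must be in [0, 1)")
        unknown = set(self.flag_rates) - set(FLAG_ORDER)
        if unknown:
            raise ValueError(f"unknown flag(s): {sorted(unknown)}")
        self.flag_rates = {f: float(self.flag_rates.get(f, 0.0)) for f in FLAG_ORDER}
        if any(not (0.0 <= p <= 1.0) for p in self.flag_rates.values()):
            raise ValueError("flag_rates must be within [0, 1]")
        if not (0.0 <= self.employment_rate <= 1.0):
            raise ValueError("employment_rate must be within [0, 1]")
        if self.outcome_scale not in ("latent", "likert6"):
            raise ValueError("outcome_scale must be 'latent' or 'likert6'")
        self.seed = int(self.seed)

    # -- convenience ---------------------------------------------------

    @property
    def correlation_matrix(self) -> np.ndarray:
        return np.asarray(self.exposure_correlation, dtype=float)

    def rng(self, component: str) -> np.random.Generator:
        """Deterministic per-component sub-stream of the global seed."""
        tag = int.from_bytes(component.encode(), "little") % (2**31)
        return np.random.default_rng([self.seed, tag])

    def replace(self, **kw) -> "SimulationConfig":
        d = asdict(self)
        d.update(kw)
        return SimulationConfig(**d)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["n_variants_per_trait"] = list(self.n_variants_per_trait)
        d["exposure_correlation"] = [list(r) for r in self.exposure_correlation]
        for k in ("maf_range", "target_r2", "true_effects",
                  "confounder_exposures", "n_invalid"):
            d[k] = list(d[k])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (see :mod:`grsmr.pipeline`).

    Either ``simulation`` is given (self-contained run) or all three input
    paths (genotypes, variants side-car, cohort) are.
    """

    out_dir: str = "grsmr_run"
    simulation: SimulationConfig | None = None
    genotypes_path: str | None = None
    variants_path: str | None = None
    cohort_path: str | None = None
    instruments_path: str | None = None
    screening: bool = True
    adjust_bmi: bool = False
    power_beta: float = 0.30
    alpha: float = 0.05
    seed: int = 0
    report_format: str = "text"

    def __post_init__(self) -> None:
        if self.simulation is not None and not isinstance(
                self.simulation, SimulationConfig):
            self.simulation = SimulationConfig(**self.simulation)
        have_paths = all(p is not None for p in
                         (self.genotypes_path, self.variants_path,
                          self.cohort_path))
        if self.simulation is None and not have_paths:
            raise ValueError("need either a simulation block or input paths")
        if self.report_format not in ("text",):
            raise ValueError("report_format must be 'text'")
        self.seed = int(self.seed)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        if self.simulation is not None:
            s = asdict(self.simulation)
            s["exposure_correlation"] = [list(r) for r in
                                         self.simulation.exposure_correlation]
            for k in ("n_variants_per_trait", "maf_range", "target_r2",
                      "true_effects", "confounder_exposures", "n_invalid"):
                s[k] = list(s[k])
            d["simulation"] = s
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))
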