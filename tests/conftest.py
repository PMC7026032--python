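import numpy as np
import pandas as pd
import pytest

from grsmr import (SimulationConfig, TRAITS, compute_unweighted_grs,
                   derive_phenotypes, simulate_cohort)

#: Covariate set used throughout the analysis stages.
COVARIATES = ("age", "sex", "centre", "tdi")


def analysis_frame(config: SimulationConfig):
    """Simulate, derive and attach the three GRS columns."""
    genotypes, cohort, instruments = simulate_cohort(config)
    data = derive_phenotypes(cohort).table
    for trait in TRAITS:
        data[f"grs_{trait}"] = compute_unweighted_grs(
            genotypes, instruments, trait).scores
    return genotypes, data, instruments


@pytest.fixture(scope="session")
def clean_cohort():
    """Mid-size cohort with no exclusions/attrition: pure estimation setting."""
    cfg = SimulationConfig(n_samples=8000, flag_rates={}, employment_rate=1.0,
                           seed=123)
    return analysis_frame(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Cohort under the default attrition and employment conditions."""
    cfg = SimulationConfig(n_samples=6000, seed=321)
    return analysis_frame(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def wald_data():
    """Six-row dataset whose TSLS slope is exactly 1 and OLS slope 14/11."""
    return pd.DataFrame({
        "G": [0.0, 0, 1, 1, 2, 2],
        "X": [0.0, 1, 1, 2, 2, 3],
        "Y": [0.0, 2, 1, 3, 2, 4],
    })
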