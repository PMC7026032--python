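"""Observational OLS, two-stage least squares MR, multivariable MR and
instrument-strength diagnostics.

The estimators are scikit-learn-style: construct with column names, call
``fit(data)`` on a DataFrame, read trailing-underscore attributes
(``params_``, ``bse_``, ``conf_int_``, ``pvalues_``, ``first_stage_f_``, ...)
or the tidy ``results_`` table.  ``fit_ols`` / ``fit_tsls`` / ``fit_mvmr``
are thin wrappers driven by a :class:`ModelSpec`.

Standard errors for the IV estimators use the standard two-stage correction:
the point estimates come from the projected (second-stage) design, but the
residual variance is computed with the *observed* exposures,
``σ̂² = (y − [X, W]β̂)'(y − [X, W]β̂) / (n − k)``, and
``Var(β̂) = σ̂² (Ẑ'Ẑ)⁻¹`` with ``Ẑ = [X̂, W]``.  The divisor is ``n − k`` by
default (``dof='n'`` reproduces tools that divide by ``n``).

Multivariable MR supports two instrumenting modes: ``"own"`` predicts each
exposure from its own risk score only (the multi-stage procedure used with
one GRS per trait), and ``"all"`` is textbook 2SLS with the full instrument
set; the Sanderson–Windmeijer conditional F always uses the full set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "ModelSpec",
    "IVFitResult",
    "OLSRegressor",
    "TSLSRegressor",
    "MVMRRegressor",
    "fit_ols",
    "fit_tsls",
    "fit_mvmr",
    "first_stage_f",
    "sw_conditional_f",
    "build_design",
]

_Z975 = float(stats.norm.ppf(0.975))


@dataclass
class ModelSpec:
    """Declarative description of one regression model.

    ``estimator`` is ``"ols"``, ``"tsls"`` or ``"mvmr"``; ``mode`` selects
    the MVMR instrumenting mode (``"own"`` or ``"all"``); ``dof`` is the
    residual-variance divisor convention (``"nk"`` → n−k, ``"n"`` → n).
    """

    outcome: str
    exposures: tuple
    instruments: tuple = ()
    covariates: tuple = ()
    estimator: str = "ols"
    mode: str = "own"
    dof: str = "nk"

    def __post_init__(self) -> None:
        self.exposures = tuple(np.atleast_1d(self.exposures))
        self.instruments = tuple(np.atleast_1d(self.instruments)) \
            if len(np.atleast_1d(self.instruments)) else ()
        self.covariates = tuple(self.covariates)
        if self.estimator not in ("ols", "tsls", "mvmr"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.estimator == "tsls":
            if len(self.exposures) != 1:
                raise ValueError("tsls takes exactly one exposure")
            if not self.instruments:
                raise ValueError("tsls requires at least one instrument")
        if self.estimator == "mvmr":
            if len(self.instruments) < len(self.exposures):
                raise ValueError("mvmr requires #instruments >= #exposures")
        if self.mode not in ("own", "all"):
            raise ValueError("mode must be 'own' or 'all'")
        if self.dof not in ("nk", "n"):
            raise ValueError("dof must be 'nk' or 'n'")


@dataclass
class IVFitResult:
    """Tidy per-term estimates plus instrument diagnostics."""

    table: pd.DataFrame
    n: int
    estimator: str
    first_stage_f: pd.Series | None = None
    conditional_f: pd.Series | None = None
    first_stage_r2: pd.Series | None = None
    sigma2: float = float("nan")

    def term(self, name: str) -> pd.Series:
        return self.table.set_index("term").loc[name]


# ---------------------------------------------------------------------------
# linear-algebra core


def build_design(data: pd.DataFrame, covariates) -> pd.DataFrame:
    """Covariate design with intercept; categorical columns are
    reference-coded (first level by sort order is the reference)."""
    parts = [pd.Series(1.0, index=data.index, name="const")]
    for c in covariates:
        col = data[c]
        if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object:
            cats = (list(col.cat.categories)
                    if isinstance(col.dtype, pd.CategoricalDtype)
                    else sorted(col.dropna().unique()))
            codes = pd.Categorical(col, categories=cats)
            dummies = pd.get_dummies(pd.Series(codes, index=data.index),
                                     prefix=c, drop_first=True, dtype=float)
            parts.append(dummies)
        else:
            parts.append(col.astype(float))
    return pd.concat(parts, axis=1)


def _solve_ls(A: np.ndarray, y: np.ndarray, what: str = "design") -> np.ndarray:
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        raise ValueError(f"rank-deficient {what} (rank {rank} < {A.shape[1]})")
    return beta

def _project(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fitted values of y on A (columns of y handled together)."""
    return A @ np.linalg.lstsq(A, y, rcond=None)[0]


def _rss(A: np.ndarray, y: np.ndarray) -> float:
    r = y - _project(A, y)
    return float(r @ r)


def _partial_f(y, W, G, dof_resid=None):
    """Partial F of the columns G added to the baseline design W."""
    full = np.column_stack([W, G])
    rss0, rss1 = _rss(W, y), _rss(full, y)
    q = G.shape[1]
    n, k = full.shape
    df2 = (n - k) if dof_resid is None else dof_resid
    return ((rss0 - rss1) / q) / (rss1 / df2), rss0, rss1


def _complete_rows(data: pd.DataFrame, cols) -> pd.DataFrame:
    return data.dropna(subset=list(dict.fromkeys(cols)))


def _fit_core(spec: ModelSpec, data: pd.DataFrame) -> IVFitResult:
    used = [spec.outcome, *spec.exposures, *spec.instruments, *spec.covariates]
    df = _complete_rows(data, used)
    y = df[spec.outcome].to_numpy(dtype=float)
    X = df[list(spec.exposures)].to_numpy(dtype=float)
    W_df = build_design(df, spec.covariates)
    W = W_df.to_numpy(dtype=float)
    n = len(df)
    k = X.shape[1] + W.shape[1]
    if n <= k:
        raise ValueError(f"n = {n} too small for {k} parameters")

    if spec.estimator == "ols":
        Z = np.column_stack([X, W])
        beta = _solve_ls(Z, y)
        resid = y - Z @ beta
        design_for_cov = Z
    else:
        G = df[list(spec.instruments)].to_numpy(dtype=float)
        # instruments must retain variance after covariate projection
        g_resid = G - _project(W, G)
        if np.any(g_resid.var(axis=0) < 1e-14):
            raise ValueError("instrument has zero partial variance after "
                             "covariate projection")
        Xhat = np.empty_like(X)
        if spec.estimator == "tsls" or spec.mode == "all":
            stage1 = np.column_stack([W, G])
            Xhat = _project(stage1, X)
        else:  # own-instrument multi-stage
            for j in range(X.shape[1]):
                stage1 = np.column_stack([W, G[:, j:j + 1]])
                Xhat[:, j] = _project(stage1, X[:, j])
        Z = np.column_stack([Xhat, W])
        beta = _solve_ls(Z, y, "second-stage design")
        resid = y - np.column_stack([X, W]) @ beta  # observed exposures
        design_for_cov = Z

    dof_resid = n - k if spec.dof == "nk" else n
    sigma2 = float(resid @ resid) / dof_resid
    xtx_inv = np.linalg.inv(design_for_cov.T @ design_for_cov)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), n - k)

    terms = list(spec.exposures) + list(W_df.columns)
    table = pd.DataFrame({
        "term": terms,
        "estimate": beta,
        "se": se,
        "ci_low": beta - _Z975 * se,
        "ci_high": beta + _Z975 * se,
        "p": pvals,
        "n": n,
    })

    fsf = fr2 = cf = None
    if spec.estimator in ("tsls", "mvmr"):
        G = df[list(spec.instruments)].to_numpy(dtype=float)
        fsf, fr2 = _first_stage_stats(spec, X, G, W)
        if spec.estimator == "mvmr":
            cf = _conditional_f(spec, X, G, W)
    return IVFitResult(table=table, n=n, estimator=spec.estimator,
                       first_stage_f=fsf, conditional_f=cf,
                       first_stage_r2=fr2, sigma2=sigma2)


def _own_instruments(spec: ModelSpec, j: int) -> list[int]:
    """Indices of the instruments for exposure j (positional pairing in own
    mode; all instruments for single-exposure TSLS)."""
    if spec.estimator == "tsls" or len(spec.exposures) == 1:
        return list(range(len(spec.instruments)))
    return [j]


def _first_stage_stats(spec, X, G, W):
    fvals, r2vals = {}, {}
    for j, name in enumerate(spec.exposures):
        idx = _own_instruments(spec, j)
        f, rss0, rss1 = _partial_f(X[:, j], W, G[:, idx])
        fvals[name] = f
        tss = float(((X[:, j] - X[:, j].mean()) ** 2).sum())
        r2vals[name] = 1.0 - rss1 / tss
    return (pd.Series(fvals, name="first_stage_f"),
            pd.Series(r2vals, name="first_stage_r2"))


def _conditional_f(spec, X, G, W):
    """Sanderson–Windmeijer conditional F per exposure (full instrument set).

    For exposure j: estimate its relation to the other exposures by 2SLS
    with all instruments, residualise, then take the instruments' joint F in
    a regression of that residual, with numerator degrees of freedom
    #instruments − #exposures + 1.
    """
    n_exp, n_inst = X.shape[1], G.shape[1]
    q = n_inst - n_exp + 1
    if q < 1:
        raise ValueError("conditional F requires #instruments >= #exposures")
    out = {}
    full = np.column_stack([W, G])
    for j, name in enumerate(spec.exposures):
        others = np.delete(X, j, axis=1)
        if others.shape[1] == 0:
            f, *_ = _partial_f(X[:, j], W, G)
            out[name] = f
            continue
        others_hat = _project(full, others)
        delta = _solve_ls(np.column_stack([others_hat, W]), X[:, j],
                          "conditional first stage")
        e = X[:, j] - np.column_stack([others, W]) @ delta
        rss0, rss1 = _rss(W, e), _rss(full, e)
        if rss0 <= 1e-12 * (float(X[:, j] @ X[:, j]) + 1.0):
            out[name] = 0.0  # exposure fully explained: no residual signal
            continue
        df2 = e.shape[0] - full.shape[1]
        out[name] = ((rss0 - rss1) / q) / (rss1 / df2)
    return pd.Series(out, name="conditional_f")


# ---------------------------------------------------------------------------
# estimators


class _LinearModelBase(BaseEstimator):
    """Shared fit/inspection machinery for the three estimators."""

    _estimator_kind = "ols"

    def _spec(self) -> ModelSpec:
        raise NotImplementedError

    def fit(self, data: pd.DataFrame, y=None):
        """Fit on a DataFrame holding outcome, exposures, instruments and
        covariates; rows with missing values in any used column are dropped."""
        spec = self._spec()
        res = _fit_core(spec, data)
        self.results_ = res
        tab = res.table.set_index("term")
        self.params_ = tab["estimate"]
        self.bse_ = tab["se"]
        self.conf_int_ = tab[["ci_low", "ci_high"]]
        self.pvalues_ = tab["p"]
        self.nobs_ = res.n
        if res.first_stage_f is not None:
            self.first_stage_f_ = res.first_stage_f
            self.first_stage_r2_ = res.first_stage_r2
        if res.conditional_f is not None:
            self.conditional_f_ = res.conditional_f
        return self

    def predict(self, data: pd.DataFrame) -> pd.Series:
        """Structural prediction from observed exposures and covariates."""
        spec = self._spec()
        df = _complete_rows(data, [*spec.exposures, *spec.covariates])
        Z = np.column_stack([
            df[list(spec.exposures)].to_numpy(dtype=float),
            build_design(df, spec.covariates).to_numpy(dtype=float)])
        return pd.Series(Z @ self.params_.to_numpy(), index=df.index,
                         name=spec.outcome)


class OLSRegressor(_LinearModelBase):
    """Observational linear regression with classical SEs.

    Supports one exposure (univariable) or several (multivariable), with
    reference-coded categorical covariates.
    """

    def __init__(self, outcome="job_satisfaction", exposures=("z_neuroticism",),
                 covariates=(), dof="nk"):
        self.outcome = outcome
        self.exposures = exposures
        self.covariates = covariates
        self.dof = dof

    def _spec(self) -> ModelSpec:
        return ModelSpec(self.outcome, tuple(np.atleast_1d(self.exposures)),
                         (), tuple(self.covariates), "ols", dof=self.dof)


class TSLSRegressor(_LinearModelBase):
    """Univariable two-stage least squares with corrected IV SEs.

    The first stage regresses the exposure on the instrument(s) and
    covariates; the second regresses the outcome on the predicted exposure
    and the same covariates.  SEs use observed-exposure residuals.
    """

    def __init__(self, outcome="job_satisfaction", exposure="z_neuroticism",
                 instruments=("grs_neuroticism",), covariates=(), dof="nk"):
        self.outcome = outcome
        self.exposure = exposure
        self.instruments = instruments
        self.covariates = covariates
        self.dof = dof

    def _spec(self) -> ModelSpec:
        return ModelSpec(self.outcome, (self.exposure,),
                         tuple(np.atleast_1d(self.instruments)),
                         tuple(self.covariates), "tsls", dof=self.dof)


class MVMRRegressor(_LinearModelBase):
    """Multivariable MR: direct effects of several exposures jointly.

    ``mode='own'`` predicts each exposure from its own (positionally paired)
    instrument, reproducing the multi-stage one-GRS-per-trait procedure;
    ``mode='all'`` is textbook 2SLS with the full instrument set.  The
    Sanderson–Windmeijer conditional F per exposure is reported either way.
    """

    def __init__(self, outcome="job_satisfaction",
                 exposures=("z_neuroticism", "z_education", "z_met"),
                 instruments=("grs_neuroticism", "grs_education",
                              "grs_activity"),
                 covariates=(), mode="own", dof="nk"):
        self.outcome = outcome
        self.exposures = exposures
        self.instruments = instruments
        self.covariates = covariates
        self.mode = mode
        self.dof = dof

    def _spec(self) -> ModelSpec:
        return ModelSpec(self.outcome, tuple(self.exposures),
                         tuple(self.instruments), tuple(self.covariates),
                         "mvmr", mode=self.mode, dof=self.dof)


# ---------------------------------------------------------------------------
# thin functional wrappers


def fit_ols(spec: ModelSpec, data: pd.DataFrame) -> IVFitResult:
    """Least-squares fit of the spec's outcome on exposures + covariates."""
    spec = ModelSpec(spec.outcome, spec.exposures, (), spec.covariates,
                     "ols", dof=spec.dof)
    return _fit_core(spec, data)


def fit_tsls(spec: ModelSpec, data: pd.DataFrame) -> IVFitResult:
    """Univariable TSLS per the spec (one exposure, ≥1 instrument)."""
    spec = ModelSpec(spec.outcome, spec.exposures, spec.instruments,
                     spec.covariates, "tsls", dof=spec.dof)
    return _fit_core(spec, data)


def fit_mvmr(spec: ModelSpec, data: pd.DataFrame) -> IVFitResult:
    """Multivariable MR per the spec."""
    spec = ModelSpec(spec.outcome, spec.exposures, spec.instruments,
                     spec.covariates, "mvmr", mode=spec.mode, dof=spec.dof)
    return _fit_core(spec, data)


def first_stage_f(spec: ModelSpec, data: pd.DataFrame) -> pd.Series:
    """Partial F of the excluded instrument(s) per exposure.

    Compares ``exposure ~ instruments + covariates`` against
    ``exposure ~ covariates``; with a single instrument this equals the
    squared first-stage t-statistic.
    """
    used = [*spec.exposures, *spec.instruments, *spec.covariates]
    df = _complete_rows(data, used)
    X = df[list(spec.exposures)].to_numpy(dtype=float)
    G = df[list(spec.instruments)].to_numpy(dtype=float)
    W = build_design(df, spec.covariates).to_numpy(dtype=float)
    f, _ = _first_stage_stats(spec, X, G, W)
    return f


def sw_conditional_f(spec: ModelSpec, data: pd.DataFrame) -> pd.Series:
    """Sanderson–Windmeijer conditional F per exposure (full instrument set)."""
    used = [*spec.exposures, *spec.instruments, *spec.covariates]
    df = _complete_rows(data, used)
    X = df[list(spec.exposures)].to_numpy(dtype=float)
    G = df[list(spec.instruments)].to_numpy(dtype=float)
    W = build_design(df, spec.covariates).to_numpy(dtype=float)
    return _conditional_f(spec, X, G, W)
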