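"""Dose-effect models for bird abundance and diversity.

Wires the census/dose tables into the mixed-model fitters: a Poisson GLMM
for the total number of birds (TNB) and a Gaussian LMM for Simpson's index,
both with the dose predictor log10-transformed and all continuous inputs
standardised by two standard deviations (so a one-unit change corresponds to
a low-to-high contrast comparable with a binary predictor).  Wind is an
unordered six-level categorical with category 0 as reference.

Coefficients are reported on both scales: the standardised fit, and an
unstandardised refit of the fixed effects with the variance parameters held
at the standardised fit's estimates (2-SD standardisation is a full-rank
affine reparameterisation of the design, under which the profiled
(RE)ML/Laplace criterion in the variance parameters is invariant).

The headline transforms turn the unstandardised dose slope into readily
interpretable effect sizes: for the log-link GLMM a percent change in
expected abundance per unit log10 dose, for the identity-link LMM
percentage points of diversity per unit log10 dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glmm import PoissonGLMMFit, fit_poisson_glmm
from .lmm import GaussianLMMFit, fit_gaussian_lmm

__all__ = [
    "ModelSpec",
    "FittedEffectModel",
    "two_sd_standardize",
    "screen_collinearity",
    "build_design",
    "fit_effect_model",
    "wald_and_satterthwaite_tests",
    "percent_change_glmm",
    "linear_percent_lmm",
    "select_random_structure_aic",
]

#: default fixed-effect structure shared by the abundance and diversity models
DEFAULT_PREDICTORS = (
    "log10_TD", "time", "time_sq", "cloud", "temperature",
    "altitude", "grass", "farmland", "coniferous",
)


@dataclass
class ModelSpec:
    """Specification of a dose-effect mixed model.

    ``predictors`` are continuous columns ("time_sq" is derived as the square
    of standardised time and must not be a data column); ``categorical`` maps
    column name to reference level; ``random_factors`` lists grouping columns
    receiving random intercepts; ``family`` is ``"poisson-log"`` or
    ``"gaussian-identity"``.
    """

    response: str
    predictors: tuple = DEFAULT_PREDICTORS
    categorical: dict = field(default_factory=lambda: {"wind": 0})
    random_factors: tuple = ("site", "day_transect")
    family: str = "poisson-log"
    standardize: bool = True


@dataclass
class FittedEffectModel:
    """A fitted GLMM/LMM with coefficients on both predictor scales."""

    spec: ModelSpec
    fit_std: PoissonGLMMFit | GaussianLMMFit
    fit_raw: PoissonGLMMFit | GaussianLMMFit
    scaling: dict  # predictor -> (mean, sd) used for standardisation
    data_ranges: dict

    @property
    def names(self):
        return self.fit_std.names

    def coef(self, scale: str = "std"):
        f = self.fit_std if scale == "std" else self.fit_raw
        return dict(zip(f.names, f.coef))

    def se(self, scale: str = "std"):
        f = self.fit_std if scale == "std" else self.fit_raw
        return dict(zip(f.names, f.se))

    @property
    def variance_components(self):
        return {g: s**2 for g, s in self.fit_std.sigma.items()}

    @property
    def aic(self):
        return self.fit_std.aic

    @property
    def loglik(self):
        return self.fit_std.loglik

    def summary_table(self) -> pd.DataFrame:
        t = wald_and_satterthwaite_tests(self)
        raw = self.coef("raw")
        t["estimate_raw"] = [raw.get(n, np.nan) for n in t["term"]]
        return t


def two_sd_standardize(x):
    """Standardise a vector to mean 0, SD 0.5: ``(x - mean) / (2 sd)``.

    Division by two standard deviations makes the slope of a continuous
    predictor directly comparable with that of a binary one.
    """
    x = np.asarray(x, dtype=float)
    m = float(x.mean())
    s = float(x.std(ddof=1))
    if s == 0:
        raise ValueError("cannot standardise a constant vector")
    return (x - m) / (2.0 * s), m, s


def screen_collinearity(predictors: pd.DataFrame, r_threshold: float = 0.87):
    """Drop the later-listed member of every highly correlated predictor pair.

    Returns ``(retained, dropped_pairs)`` where ``dropped_pairs`` lists
    ``(kept, dropped, r)`` tuples for every pair with ``|r| >= r_threshold``.
    """
    cols = list(predictors.columns)
    if len(cols) < 2:
        return cols, []
    corr = predictors.corr().to_numpy()
    dropped: set = set()
    pairs = []
    for i in range(len(cols)):
        if cols[i] in dropped:
            continue
        for j in range(i + 1, len(cols)):
            if cols[j] in dropped:
                continue
            r = corr[i, j]
            if np.isfinite(r) and abs(r) >= r_threshold:
                dropped.add(cols[j])
                pairs.append((cols[i], cols[j], float(r)))
    return [c for c in cols if c not in dropped], pairs


def build_design(data: pd.DataFrame, spec: ModelSpec, standardize: bool | None = None):
    """Assemble the fixed-effects design matrix for a model spec.

    Returns ``(y, X, names, scaling)``; ``scaling`` maps each continuous
    predictor to the (mean, sd) it was standardised with (empty when raw).
    The quadratic time term is the square of the (standardised) time column.
    """
    if standardize is None:
        standardize = spec.standardize
    y = data[spec.response].to_numpy(dtype=float)
    cols = [np.ones(len(data))]
    names = ["(Intercept)"]
    scaling: dict = {}

    base = {}
    for name in spec.predictors:
        if name == "time_sq":
            continue
        x = data[name].to_numpy(dtype=float)
        if standardize:
            x, m, s = two_sd_standardize(x)
            scaling[name] = (m, s)
        base[name] = x
    for name in spec.predictors:
        if name == "time_sq":
            cols.append(base["time"] ** 2)
        else:
            cols.append(base[name])
        names.append(name)
    for cat, ref in spec.categorical.items():
        levels = np.sort(data[cat].unique())
        for lev in levels:
            if lev == ref:
                continue
            cols.append((data[cat] == lev).to_numpy(dtype=float))
            names.append(f"{cat}{lev}")
    X = np.column_stack(cols)
    return y, X, names, scaling


def fit_effect_model(data: pd.DataFrame, spec: ModelSpec) -> FittedEffectModel:
    """Fit a dose-effect model on the standardised scale, refit raw.

    Site-years lacking a dose (no birds observed, hence no abundance-weighted
    dose) are dropped before fitting.
    """
    needed = [spec.response] + [p for p in spec.predictors if p != "time_sq"]
    data = data.dropna(subset=[c for c in needed if c in data.columns])
    factors = {g: data[g].to_numpy() for g in spec.random_factors}

    y, X, names, scaling = build_design(data, spec, standardize=True)
    if spec.family == "poisson-log":
        fit_std = fit_poisson_glmm(y, X, factors, names=names)
        fix = dict(fit_std.sigma)
    elif spec.family == "gaussian-identity":
        fit_std = fit_gaussian_lmm(y, X, factors, names=names)
        fix = dict(fit_std.sigma)
        fix["resid"] = fit_std.sigma_resid
    else:
        raise ValueError(f"unknown family {spec.family!r}")

    y2, X2, names2, _ = build_design(data, spec, standardize=False)
    if spec.family == "poisson-log":
        fit_raw = fit_poisson_glmm(y2, X2, factors, names=names2, fix_sigma=fix)
    else:
        fit_raw = fit_gaussian_lmm(y2, X2, factors, names=names2, fix_sigma=fix)

    ranges = {
        p: (float(data[p].min()), float(data[p].max()))
        for p in spec.predictors
        if p != "time_sq" and p in data.columns
    }
    return FittedEffectModel(
        spec=spec, fit_std=fit_std, fit_raw=fit_raw, scaling=scaling,
        data_ranges=ranges,
    )


def wald_and_satterthwaite_tests(model: FittedEffectModel | PoissonGLMMFit | GaussianLMMFit) -> pd.DataFrame:
    """Coefficient tests: Wald z for the GLMM, Satterthwaite t for the LMM."""
    fit = model.fit_std if isinstance(model, FittedEffectModel) else model
    if isinstance(fit, PoissonGLMMFit):
        t = fit.wald_table()
        return pd.DataFrame(
            {"term": t["names"], "estimate": t["estimate"], "se": t["se"],
             "z": t["z"], "p": t["p"]}
        )
    t = fit.t_table()
    return pd.DataFrame(
        {"term": t["names"], "estimate": t["estimate"], "se": t["se"],
         "t": t["t"], "df": t["df"], "p": t["p"]}
    )


def percent_change_glmm(b_unstd: float, se: float, z: float = 1.96):
    """Percent change in expected response per unit predictor (log link).

    Returns ``(point, lo, hi)`` where point = 100 (exp(b) - 1) and the CI
    endpoints apply the same transform to ``b -/+ z se``.
    """
    if se <= 0:
        raise ValueError("standard error must be positive")
    point = 100.0 * (np.exp(b_unstd) - 1.0)
    lo = 100.0 * (np.exp(b_unstd - z * se) - 1.0)
    hi = 100.0 * (np.exp(b_unstd + z * se) - 1.0)
    return float(point), float(lo), float(hi)


def linear_percent_lmm(b_unstd: float, se: float, z: float = 1.96):
    """Percentage-point change per unit predictor for an identity link."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    return (
        float(100.0 * b_unstd),
        float(100.0 * (b_unstd - z * se)),
        float(100.0 * (b_unstd + z * se)),
    )


def select_random_structure_aic(
    data: pd.DataFrame, spec: ModelSpec, candidates: list
):
    """Choose among candidate random-intercept structures by AIC.

    ``candidates`` is a list of tuples of grouping-column names.  All
    candidates are fitted by ML (for the Gaussian family ``reml=False``) so
    their AICs are comparable; ties and failures resolve to the earliest
    listed converged candidate.  Returns ``(best_structure, table)``.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate structures")
    needed = [spec.response] + [p for p in spec.predictors if p != "time_sq"]
    data = data.dropna(subset=[c for c in needed if c in data.columns])
    y, X, names, _ = build_design(data, spec, standardize=True)
    rows = []
    for struct in candidates:
        factors = {g: data[g].to_numpy() for g in struct}
        try:
            if spec.family == "poisson-log":
                fit = fit_poisson_glmm(y, X, factors, names=names)
            else:
                fit = fit_gaussian_lmm(y, X, factors, names=names, reml=False,
                                       satterthwaite=False)
            rows.append({"structure": tuple(struct), "aic": fit.aic,
                         "loglik": fit.loglik, "converged": True})
        except (RuntimeError, ValueError) as err:  # recorded, excluded
            rows.append({"structure": tuple(struct), "aic": np.nan,
                         "loglik": np.nan, "converged": False,
                         "error": str(err)})
    table = pd.DataFrame(rows)
    ok = table[table["converged"]]
    if ok.empty:
        raise RuntimeError("no candidate random structure converged")
    best = ok.loc[ok["aic"].idxmin(), "structure"]
    return tuple(best), table
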