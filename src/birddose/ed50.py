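"""ED50 estimation from the fitted abundance GLMM.

The total dose halving the expected number of birds is estimated by
simulation: the fitted GLMM predicts expected abundance over a grid of doses
spanning the calculated dose range (all other covariates at their means,
wind at the reference category); each predicted curve is perturbed with the
model's own stochastic layers (normal random intercepts on the link scale,
then Poisson observation noise); a three-parameter log-logistic curve

    f(d) = c / (1 + exp(b (ln d - ln e)))

with lower asymptote fixed at 0 and b, c, e > 0 is fitted to every perturbed
curve by least squares; the per-curve dose ``e`` at which the curve reaches
half its own upper asymptote (f(e) = c/2 exactly) is the replicate ED50, and
the replicates are summarised by their median and a 2.5/97.5 percentile
interval.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import optimize

from .effects import FittedEffectModel

__all__ = [
    "LogLogisticFit",
    "ED50Summary",
    "predict_response_curve",
    "perturb_with_random_errors",
    "fit_log_logistic",
    "estimate_ed50",
]


@dataclass
class LogLogisticFit:
    """A constrained three-parameter log-logistic fit (lower limit 0)."""

    b: float  # slope, > 0 for a response decreasing in dose
    c: float  # upper asymptote, > 0
    e: float  # ED50 on the dose scale, > 0
    rss: float
    converged: bool

    def predict(self, dose):
        d = np.asarray(dose, dtype=float)
        return self.c / (1.0 + np.exp(self.b * (np.log(d) - np.log(self.e))))


@dataclass
class ED50Summary:
    """Replicate-based ED50 point estimate and percentile CI (Gy)."""

    point: float
    ci_low: float
    ci_high: float
    B: int
    seed: int
    fraction_converged: float

    def to_dict(self):
        return asdict(self)


def _dose_linear_predictor(model: FittedEffectModel, doses, dose_term: str = "log10_TD"):
    coef = model.coef("std")
    m, s = model.scaling[dose_term]
    z = (np.log10(doses) - m) / (2.0 * s)
    return coef["(Intercept)"] + coef[dose_term] * z


def predict_response_curve(model: FittedEffectModel, doses, dose_term: str = "log10_TD"):
    """Expected response over a dose grid, other covariates at their means.

    Standardised covariates sit at 0 (their mean) and the wind category at
    its reference, so the linear predictor reduces to the intercept plus the
    dose term; a log-link model returns ``exp`` of it.  Strictly decreasing
    in dose whenever the dose slope is negative.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    eta = _dose_linear_predictor(model, doses, dose_term)
    if model.spec.family == "poisson-log":
        return np.exp(eta)
    return eta


def perturb_with_random_errors(
    curve,
    variance_components: dict,
    rng: np.random.Generator,
    poisson: bool = True,
):
    """Perturb a predicted mean curve with the GLMM's stochastic layers.

    Each dose point receives independent normal random intercepts on the log
    scale (one draw per variance component) and, unless ``poisson=False``, a
    Poisson count at the perturbed mean.  With all variances zero and
    ``poisson=False`` the curve is returned unchanged.  Note the expectation
    over draws is the curve times ``exp(total_variance / 2)`` (lognormal mean
    correction), not the curve itself.
    """
    curve = np.asarray(curve, dtype=float)
    total_var = 0.0
    log_mu = np.log(curve)
    for v in variance_components.values():
        if v < 0:
            raise ValueError("variance components must be non-negative")
        total_var += v
        if v > 0:
            log_mu = log_mu + rng.normal(0.0, np.sqrt(v), size=curve.shape)
    mu = np.exp(log_mu)
    if poisson:
        return rng.poisson(mu).astype(float)
    return mu


def fit_log_logistic(doses, responses, fixed_c: float | None = None) -> LogLogisticFit:
    """Least-squares constrained log-logistic fit with lower asymptote 0.

    Requires at least four dose points.  With ``fixed_c`` the upper
    asymptote is pinned (two free parameters, b and e); otherwise all three
    are estimated.  Positivity of b, c and e is enforced by optimising on
    the log scale.  A fit is flagged unconverged when the optimiser fails or
    the data show no decline with dose (slope collapsing to zero).

    When the response declines like a pure power of dose — as the log-link
    abundance model predicts — c and e are jointly unidentifiable (only
    ``c e^b`` is determined), so per-replicate ED50 estimation must supply
    ``fixed_c``; the free three-parameter form is appropriate for genuinely
    sigmoidal data.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(d) < 4:
        raise ValueError("need at least four dose points")
    if np.any(d <= 0):
        raise ValueError("doses must be positive")
    logd = np.log(d)

    order = np.argsort(d)
    top = fixed_c if fixed_c is not None else max(
        float(np.mean(y[order][: max(3, len(d) // 10)])), 1e-8
    )
    half = top / 2.0
    below = y <= half
    e0 = float(np.exp(logd[below][0])) if below.any() else float(np.exp(logd.mean()))
    e0 = max(e0, 1e-12)

    if fixed_c is not None:
        if fixed_c <= 0:
            raise ValueError("fixed upper asymptote must be positive")

        def resid(params):
            b, e = np.exp(np.clip(params, -600.0, 600.0))
            loge = np.log(e) if e > 0 else -700.0
            return fixed_c / (1.0 + np.exp(np.clip(b * (logd - loge), -500, 500))) - y

        res = optimize.least_squares(resid, x0=np.log([1.0, e0]), method="lm", max_nfev=2000)
        b, e = np.exp(np.clip(res.x, -600.0, 600.0))
        c = fixed_c
    else:

        def resid(params):
            b, c_, e = np.exp(np.clip(params, -600.0, 600.0))
            loge = np.log(e) if e > 0 else -700.0
            return c_ / (1.0 + np.exp(np.clip(b * (logd - loge), -500, 500))) - y

        res = optimize.least_squares(
            resid, x0=np.log([1.0, top, e0]), method="lm", max_nfev=2000
        )
        b, c, e = np.exp(np.clip(res.x, -600.0, 600.0))
    rss = float(2 * res.cost)
    declining = bool(np.all(np.isfinite([b, c, e])) and b > 1e-4 and c > 1e-8)
    return LogLogisticFit(
        b=float(b), c=float(c), e=float(e), rss=rss,
        converged=bool(res.success and declining),
    )


def estimate_ed50(
    model: FittedEffectModel,
    B: int = 1000,
    grid: int = 100,
    seed: int = 0,
    dose_range: tuple | None = None,
    dose_term: str = "log10_TD",
    poisson: bool = True,
    include_random: bool = True,
) -> ED50Summary:
    """Replicate ED50 estimate from a fitted abundance GLMM.

    Generates ``B`` perturbed dose-response curves over a uniform grid of
    ``grid`` doses spanning ``dose_range`` (default: the range of calculated
    total doses the model was fitted to), fits the constrained log-logistic
    to each, and summarises the accepted per-curve ED50s by their median and
    2.5/97.5 percentiles.  Aborts if more than half the fits fail.

    Each replicate fit pins the upper asymptote to the model's expected
    abundance at the minimum grid dose (corrected for the lognormal mean of
    the random-intercept perturbation), so the replicate ED50 is the dose at
    which expected abundance halves relative to the low-dose end of the
    calculated range.  Replicates whose ED50 falls outside the dose grid are
    rejected along with non-convergent fits.
    """
    if B < 100:
        raise ValueError("need at least 100 replicates")
    if dose_range is None:
        lo10, hi10 = model.data_ranges[dose_term]
        dose_range = (10.0**lo10, 10.0**hi10)
    dmin, dmax = dose_range
    if not (0 < dmin < dmax):
        raise ValueError("invalid dose range")
    doses = np.linspace(dmin, dmax, grid)
    curve = predict_response_curve(model, doses, dose_term)
    vcomp = model.variance_components if include_random else {}
    total_var = float(sum(vcomp.values()))
    c_pin = float(curve[0] * np.exp(total_var / 2.0))

    rng = np.random.default_rng(seed)
    ed50s = []
    n_ok = 0
    for _ in range(B):
        y = perturb_with_random_errors(curve, vcomp, rng, poisson=poisson)
        try:
            fit = fit_log_logistic(doses, y, fixed_c=c_pin)
        except ValueError:
            continue
        if fit.converged and dmin <= fit.e <= dmax:
            n_ok += 1
            ed50s.append(fit.e)
    frac = n_ok / B
    if frac < 0.5:
        raise RuntimeError(
            f"only {n_ok}/{B} log-logistic fits converged; ED50 summary aborted"
        )
    ed50s = np.asarray(ed50s)
    return ED50Summary(
        point=float(np.median(ed50s)),
        ci_low=float(np.percentile(ed50s, 2.5)),
        ci_high=float(np.percentile(ed50s, 97.5)),
        B=B, seed=seed, fraction_converged=frac,
    )
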