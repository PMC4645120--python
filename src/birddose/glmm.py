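"""Poisson generalized linear mixed model with crossed random intercepts.

Fits ``y ~ Poisson(exp(X beta + Z u))`` where ``u`` collects independent
random intercepts for one or more (possibly crossed) grouping factors,
``u_g ~ N(0, sigma_g^2 I)``.  The marginal likelihood is approximated by the
Laplace method: for candidate variance parameters the penalised joint
log-likelihood is maximised over ``(beta, u)`` by Newton iterations with
step-halving, and the profiled Laplace objective

    l(theta) = logp(y | beta*, u*) - u*' Lambda^-1 u* / 2
               - log|Lambda|/2 - log|Z'WZ + Lambda^-1|/2

is maximised over ``theta = log sigma`` by quasi-Newton search.  Standard
errors of the fixed effects come from the fixed-effects block of the inverse
joint Hessian at the mode, which accounts for the uncertainty of the random
effects given the variance estimates.

Problem sizes here (a thousand or so observations, a few hundred random
levels) are small enough that dense linear algebra is the fastest option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, special, stats

__all__ = ["PoissonGLMMFit", "fit_poisson_glmm"]

_ETA_CLIP = 30.0


@dataclass
class PoissonGLMMFit:
    """Result of a Poisson GLMM (or plain GLM) fit."""

    coef: np.ndarray
    se: np.ndarray
    names: list
    vcov: np.ndarray
    sigma: dict  # factor name -> random-intercept standard deviation
    ranef: dict  # factor name -> posterior-mode random intercepts
    loglik: float
    aic: float
    n_obs: int
    converged: bool
    grad_norm: float
    n_params: int = 0

    def wald_table(self):
        """Per-coefficient Wald z statistics and two-sided normal p-values."""
        if np.any(self.se == 0):
            raise ValueError("zero standard error: Wald statistic undefined")
        z = self.coef / self.se
        p = 2 * stats.norm.sf(np.abs(z))
        return {"names": list(self.names), "estimate": self.coef, "se": self.se, "z": z, "p": p}


def _build_z(factors: dict, n: int):
    names, codes, sizes = [], [], []
    for name, c in factors.items():
        c = np.asarray(c)
        if c.ndim != 1 or len(c) != n:
            raise ValueError(f"factor {name!r} must be a length-{n} vector of codes")
        u, inv = np.unique(c, return_inverse=True)
        if len(u) < 2:
            raise ValueError(f"random factor {name!r} needs >= 2 levels")
        names.append(name)
        codes.append(inv)
        sizes.append(len(u))
    q = int(np.sum(sizes))
    Z = np.zeros((n, q))
    off = 0
    offsets = []
    for inv, sz in zip(codes, sizes):
        Z[np.arange(n), off + inv] = 1.0
        offsets.append(off)
        off += sz
    return Z, names, sizes, offsets


def _penalized_loglik(y, eta, x, dpen, logyfact):
    mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
    return float(y @ eta - mu.sum() - logyfact - 0.5 * (dpen * x * x).sum())


def _inner_newton(y, A, dpen, x0, logyfact, tol=1e-9, max_iter=60):
    """Maximise the penalised joint log-likelihood over (beta, u)."""
    x = x0.copy()
    f = _penalized_loglik(y, A @ x, x, dpen, logyfact)
    H = None
    for _ in range(max_iter):
        eta = np.clip(A @ x, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        grad = A.T @ (y - mu) - dpen * x
        B = A * np.sqrt(mu)[:, None]
        H = B.T @ B
        H[np.diag_indices_from(H)] += dpen
        try:
            c, low = linalg.cho_factor(H, check_finite=False)
            step = linalg.cho_solve((c, low), grad, check_finite=False)
        except linalg.LinAlgError:
            step = linalg.lstsq(H, grad, check_finite=False)[0]
        gmax = np.max(np.abs(grad))
        if gmax < tol * max(1.0, abs(f)):
            return x, f, H, gmax, True
        t = 1.0
        for _ in range(30):
            xn = x + t * step
            fn = _penalized_loglik(y, A @ xn, xn, dpen, logyfact)
            if fn >= f - 1e-12:
                break
            t *= 0.5
        if fn < f - 1e-8:
            break
        x, f = xn, fn
    eta = np.clip(A @ x, -_ETA_CLIP, _ETA_CLIP)
    grad = A.T @ (y - np.exp(eta)) - dpen * x
    gmax = float(np.max(np.abs(grad)))
    return x, f, H, gmax, gmax < 1e-4 * max(1.0, abs(f))


def fit_poisson_glmm(
    y,
    X,
    factors: dict | None = None,
    names: list | None = None,
    start_sigma: float = 0.3,
    fix_sigma: dict | None = None,
    log_sigma_bounds=(-6.0, 4.0),
) -> PoissonGLMMFit:
    """Fit a Poisson log-link mixed model by Laplace-approximated ML.

    Parameters
    ----------
    y, X
        Non-negative integer response and dense fixed-effects design matrix
        (include the intercept column yourself).
    factors
        Mapping of factor name to a length-n vector of group codes, one
        random intercept per factor; factors may be crossed.  ``None`` or
        empty fits a plain Poisson GLM by Newton iteration.
    fix_sigma
        Mapping of factor name to a fixed random-intercept SD.  When every
        factor is fixed the outer variance optimisation is skipped — used to
        re-estimate fixed effects on another predictor scale at the variance
        estimates of a reference fit.

    Returns
    -------
    PoissonGLMMFit
        Coefficients, SEs, variance components, Laplace log-likelihood and
        AIC (``-2 loglik + 2 (p + n_variance_params)``).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("response and design matrix disagree on n")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("response must consist of non-negative integers")
    if y.sum() == 0:
        raise ValueError("degenerate response: all counts are zero")
    if names is None:
        names = [f"x{j}" for j in range(p)]
    logyfact = float(special.gammaln(y + 1).sum())

    if not factors:
        x, f, H, gmax, ok = _inner_newton(y, X, np.zeros(p), _init_beta(y, p), logyfact)
        if not ok:
            raise RuntimeError(f"Poisson GLM failed to converge (max|grad| = {gmax:.3g})")
        vcov = linalg.inv(H)
        ll = f  # no penalty when dpen = 0
        return PoissonGLMMFit(
            coef=x, se=np.sqrt(np.diag(vcov)), names=list(names), vcov=vcov,
            sigma={}, ranef={}, loglik=ll, aic=-2 * ll + 2 * p, n_obs=n,
            converged=True, grad_norm=gmax, n_params=p,
        )

    Z, fnames, sizes, offsets = _build_z(factors, n)
    q = Z.shape[1]
    A = np.hstack([X, Z])
    fix_sigma = dict(fix_sigma or {})
    free = [g for g in fnames if g not in fix_sigma]

    state = {"x": np.concatenate([_init_beta(y, p), np.zeros(q)])}

    def _dpen(sigmas):
        d = np.zeros(p + q)
        for g, sz, off in zip(fnames, sizes, offsets):
            d[p + off : p + off + sz] = 1.0 / sigmas[g] ** 2
        return d

    def _profiled(log_sig_free):
        sigmas = dict(fix_sigma)
        sigmas.update({g: float(np.exp(s)) for g, s in zip(free, log_sig_free)})
        dpen = _dpen(sigmas)
        x, f, H, gmax, ok = _inner_newton(y, A, dpen, state["x"], logyfact)
        if ok:
            state["x"] = x
        Huu = H[p:, p:]
        sign, logdet_huu = np.linalg.slogdet(Huu)
        if sign <= 0:
            return np.inf, None
        logdet_lam = 2.0 * sum(
            sz * np.log(sigmas[g]) for g, sz in zip(fnames, sizes)
        )
        ll = f - 0.5 * logdet_lam - 0.5 * logdet_huu
        return -ll, (x, H, gmax, sigmas)

    if free:
        x0 = np.log(np.full(len(free), start_sigma))
        res = optimize.minimize(
            lambda t: _profiled(t)[0],
            x0,
            method="L-BFGS-B",
            bounds=[log_sigma_bounds] * len(free),
            options={"maxiter": 200, "ftol": 1e-11, "gtol": 1e-7},
        )
        neg_ll, aux = _profiled(res.x)
        outer_ok = res.success or res.status == 1  # treat maxiter hit as soft
    else:
        neg_ll, aux = _profiled(np.empty(0))
        outer_ok = True
    if aux is None:
        raise RuntimeError("Laplace objective undefined at the optimum")
    x, H, gmax, sigmas = aux
    if not np.isfinite(neg_ll):
        raise RuntimeError(f"GLMM failed to converge (max|grad| = {gmax:.3g})")

    vcov_full = linalg.inv(H)
    vcov = vcov_full[:p, :p]
    ranef = {
        g: x[p + off : p + off + sz] for g, sz, off in zip(fnames, sizes, offsets)
    }
    ll = -neg_ll
    n_params = p + len(free)
    return PoissonGLMMFit(
        coef=x[:p], se=np.sqrt(np.diag(vcov)), names=list(names), vcov=vcov,
        sigma={g: sigmas[g] for g in fnames}, ranef=ranef, loglik=ll,
        aic=-2 * ll + 2 * n_params, n_obs=n, converged=bool(outer_ok),
        grad_norm=gmax, n_params=n_params,
    )


def _init_beta(y, p):
    b = np.zeros(p)
    b[0] = np.log(max(y.mean(), 1e-8))
    return b
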