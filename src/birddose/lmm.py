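"""Gaussian linear mixed model with crossed random intercepts.

Fits ``y = X beta + sum_g Z_g u_g + e`` with independent random intercepts
``u_g ~ N(0, sigma_g^2 I)`` and residual ``e ~ N(0, sigma_e^2 I)`` by REML
(default) or ML.  The marginal covariance ``V = sigma_e^2 I + sum_g sigma_g^2
Z_g Z_g'`` is handled through the Woodbury identity, so every likelihood
evaluation costs one Cholesky factorisation of a q x q matrix (q = total
number of random levels) instead of an n x n one.

Per-coefficient t tests use Satterthwaite's approximation: the degrees of
freedom are ``2 v_i^2 / (g' C g)`` where ``v_i`` is the coefficient's
sampling variance, ``g`` its gradient with respect to the variance
components (finite differences) and ``C`` the inverse observed information
of the (RE)ML criterion in the variance components.  If that computation
degenerates (e.g. a variance estimate on the zero boundary) the residual
degrees of freedom ``n - p`` are substituted and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, stats

__all__ = ["GaussianLMMFit", "fit_gaussian_lmm"]


@dataclass
class GaussianLMMFit:
    """Result of a Gaussian LMM fit."""

    coef: np.ndarray
    se: np.ndarray
    names: list
    vcov: np.ndarray
    sigma: dict  # factor name -> random-intercept SD
    sigma_resid: float
    loglik: float  # REML or ML log-likelihood, per `reml`
    aic: float
    reml: bool
    n_obs: int
    converged: bool
    satterthwaite_df: np.ndarray | None = None
    df_fallback: bool = False

    def t_table(self):
        """Per-coefficient t statistics with Satterthwaite df and p-values."""
        if np.any(self.se == 0):
            raise ValueError("zero standard error: t statistic undefined")
        t = self.coef / self.se
        df = self.satterthwaite_df
        if df is None:
            df = np.full_like(t, float(self.n_obs - len(self.coef)))
        p = 2 * stats.t.sf(np.abs(t), df)
        return {
            "names": list(self.names), "estimate": self.coef, "se": self.se,
            "t": t, "df": df, "p": p,
        }


def _build_z(factors: dict, n: int):
    names, blocks, sizes = [], [], []
    for name, c in factors.items():
        c = np.asarray(c)
        if c.ndim != 1 or len(c) != n:
            raise ValueError(f"factor {name!r} must be a length-{n} vector of codes")
        u, inv = np.unique(c, return_inverse=True)
        if len(u) < 2:
            raise ValueError(f"random factor {name!r} needs >= 2 levels")
        Zg = np.zeros((n, len(u)))
        Zg[np.arange(n), inv] = 1.0
        names.append(name)
        blocks.append(Zg)
        sizes.append(len(u))
    return names, blocks, sizes


class _LMMWork:
    """Precomputed cross-products for repeated (RE)ML evaluations."""

    def __init__(self, y, X, blocks, sizes):
        self.y = y
        self.X = X
        self.n, self.p = X.shape
        self.sizes = sizes
        Z = np.hstack(blocks) if blocks else np.zeros((self.n, 0))
        self.q = Z.shape[1]
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ X
        self.Zty = Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def crit(self, variances, sig2e, reml):
        """Negative (RE)ML log-likelihood at the given variance components."""
        n, p, q = self.n, self.p, self.q
        gamma = np.concatenate(
            [np.full(sz, v / sig2e) for sz, v in zip(self.sizes, variances)]
        ) if q else np.zeros(0)
        sg = np.sqrt(gamma)
        M = np.eye(q) + (sg[:, None] * self.ZtZ) * sg[None, :]
        try:
            cM, low = linalg.cho_factor(M, check_finite=False)
        except linalg.LinAlgError:
            return np.inf, None
        logdet_V = n * np.log(sig2e) + 2.0 * np.log(np.diag(cM)).sum()

        def vinv_quad(Za, Zb, ab):
            # a' V^-1 b given Z'a, Z'b and a'b
            t = linalg.cho_solve((cM, low), sg[:, None] * Zb, check_finite=False)
            return (ab - (sg[:, None] * Za).T @ t) / sig2e

        XtVX = vinv_quad(self.ZtX, self.ZtX, self.XtX)
        XtVy = vinv_quad(self.ZtX, self.Zty[:, None], self.Xty[:, None])[:, 0]
        ytVy = float(vinv_quad(self.Zty[:, None], self.Zty[:, None], self.yty)[0, 0])
        try:
            cX, lowX = linalg.cho_factor(XtVX, check_finite=False)
        except linalg.LinAlgError:
            return np.inf, None
        beta = linalg.cho_solve((cX, lowX), XtVy, check_finite=False)
        yPy = ytVy - XtVy @ beta
        if reml:
            logdet_XtVX = 2.0 * np.log(np.diag(cX)).sum()
            nll = 0.5 * (logdet_V + logdet_XtVX + yPy + (n - p) * np.log(2 * np.pi))
        else:
            nll = 0.5 * (logdet_V + yPy + n * np.log(2 * np.pi))
        Cbeta = linalg.cho_solve((cX, lowX), np.eye(p), check_finite=False)
        return nll, (beta, Cbeta)


def fit_gaussian_lmm(
    y,
    X,
    factors: dict | None = None,
    names: list | None = None,
    reml: bool = True,
    start_sigma: float | None = None,
    fix_sigma: dict | None = None,
    satterthwaite: bool = True,
) -> GaussianLMMFit:
    """Fit a Gaussian linear mixed model by REML (or ML).

    Parameters mirror :func:`birddose.glmm.fit_poisson_glmm`; ``factors``
    maps factor names to group-code vectors (crossed factors allowed).
    ``fix_sigma`` may pin individual random-intercept SDs (and/or the
    residual SD under key ``"resid"``), e.g. to transfer variance estimates
    between predictor scales.  AIC uses ``-2 loglik + 2 (p + n_var_params)``
    and is only comparable across fits with ``reml=False``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("response and design matrix disagree on n")
    if names is None:
        names = [f"x{j}" for j in range(p)]
    factors = factors or {}
    fnames, blocks, sizes = _build_z(factors, n)
    work = _LMMWork(y, X, blocks, sizes)
    k = len(fnames)
    fix_sigma = dict(fix_sigma or {})
    free = [g for g in fnames if g not in fix_sigma] + (
        [] if "resid" in fix_sigma else ["resid"]
    )

    sd_y = float(np.std(y)) or 1.0
    if start_sigma is None:
        start_sigma = 0.5 * sd_y

    def unpack(log_sig_free):
        s = dict(fix_sigma)
        s.update({g: float(np.exp(v)) for g, v in zip(free, log_sig_free)})
        variances = np.array([s[g] ** 2 for g in fnames])
        return variances, s["resid"] ** 2

    def objective(log_sig_free):
        variances, sig2e = unpack(log_sig_free)
        nll, _ = work.crit(variances, sig2e, reml)
        return nll

    lo, hi = np.log(sd_y) - 10.0, np.log(sd_y) + 4.0
    if free:
        x0 = np.log(np.full(len(free), start_sigma))
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=[(lo, hi)] * len(free),
            options={"maxiter": 300, "ftol": 1e-12, "gtol": 1e-8},
        )
        log_sig = res.x
        outer_ok = bool(res.success or res.status == 1)
    else:
        log_sig = np.empty(0)
        outer_ok = True
    variances, sig2e = unpack(log_sig)
    nll, aux = work.crit(variances, sig2e, reml)
    if not np.isfinite(nll) or aux is None:
        raise RuntimeError("LMM failed to converge")
    beta, Cbeta = aux
    se = np.sqrt(np.diag(Cbeta))
    n_var = len(free)
    ll = -nll
    aic = -2 * ll + 2 * (p + n_var)

    df = None
    fallback = False
    if satterthwaite:
        df, fallback = _satterthwaite_df(work, variances, sig2e, reml, Cbeta)

    return GaussianLMMFit(
        coef=beta, se=se, names=list(names), vcov=Cbeta,
        sigma={g: float(np.sqrt(v)) for g, v in zip(fnames, variances)},
        sigma_resid=float(np.sqrt(sig2e)), loglik=ll, aic=aic, reml=reml,
        n_obs=n, converged=outer_ok, satterthwaite_df=df, df_fallback=fallback,
    )


def _satterthwaite_df(work, variances, sig2e, reml, Cbeta):
    """Delta-method Satterthwaite df for each fixed-effect coefficient."""
    p = work.p
    phi = np.concatenate([variances, [sig2e]])  # variance scale
    k = len(phi)
    steps = np.maximum(1e-4 * np.abs(phi), 1e-10)

    def cbeta_at(ph):
        if np.any(ph[:-1] < 0) or ph[-1] <= 0:
            return None
        _, aux = work.crit(ph[:-1], ph[-1], reml)
        return None if aux is None else aux[1]

    def nll_at(ph):
        if np.any(ph[:-1] < 0) or ph[-1] <= 0:
            return np.inf
        val, _ = work.crit(ph[:-1], ph[-1], reml)
        return val

    try:
        # gradient of each coefficient variance w.r.t. variance components
        grads = np.zeros((p, k))
        for j in range(k):
            hp, hm = phi.copy(), phi.copy()
            hp[j] += steps[j]
            hm[j] = max(hm[j] - steps[j], hm[j] * 0.5 if j < k - 1 else hm[j] * 0.5)
            Cp, Cm = cbeta_at(hp), cbeta_at(hm)
            if Cp is None or Cm is None:
                raise FloatingPointError
            grads[:, j] = (np.diag(Cp) - np.diag(Cm)) / (hp[j] - hm[j])

        # observed information of the (RE)ML criterion in the variance components
        Hinfo = np.zeros((k, k))
        f0 = nll_at(phi)
        for i in range(k):
            for j in range(i, k):
                hi_, hj = steps[i], steps[j]
                if i == j:
                    f1 = nll_at(_bump(phi, {i: hi_}))
                    f2 = nll_at(_bump(phi, {i: -hi_}))
                    if not np.isfinite([f1, f2]).all():
                        raise FloatingPointError
                    Hinfo[i, i] = (f1 - 2 * f0 + f2) / hi_**2
                else:
                    fpp = nll_at(_bump(phi, {i: hi_, j: hj}))
                    fpm = nll_at(_bump(phi, {i: hi_, j: -hj}))
                    fmp = nll_at(_bump(phi, {i: -hi_, j: hj}))
                    fmm = nll_at(_bump(phi, {i: -hi_, j: -hj}))
                    if not np.isfinite([fpp, fpm, fmp, fmm]).all():
                        raise FloatingPointError
                    Hinfo[i, j] = Hinfo[j, i] = (fpp - fpm - fmp + fmm) / (4 * hi_ * hj)
        if not np.all(np.isfinite(Hinfo)):
            raise FloatingPointError
        Vphi = linalg.pinvh(Hinfo)
        v = np.diag(Cbeta)
        denom = np.einsum("ij,jk,ik->i", grads, Vphi, grads)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = 2.0 * v**2 / denom
        bad = ~np.isfinite(df) | (df < 1.0)
        fallback = bool(np.any(bad))
        df = np.where(bad, float(work.n - p), df)
        return df, fallback
    except (FloatingPointError, linalg.LinAlgError):
        return np.full(p, float(work.n - p)), True


def _bump(phi, deltas):
    out = phi.copy()
    for j, d in deltas.items():
        out[j] = out[j] + d
    return out
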