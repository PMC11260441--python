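"""Classical quantitative-genetics statistics.

Mid-parent regression, random-intercept linear mixed models by REML,
paired t-tests, and repeatability (intraclass correlation of repeated
measurements).  These are the frequentist companions to the Bayesian
animal model: the offspring-on-mid-parent regression slope estimates
narrow-sense heritability under additive inheritance, and repeatability
upper-bounds it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

__all__ = [
    "RegressionResult",
    "MixedModelResult",
    "PairedTResult",
    "RepeatabilityResult",
    "midparent_regression",
    "lmm_random_intercept",
    "paired_t_test",
    "repeatability",
]


@dataclass(frozen=True)
class RegressionResult:
    params: dict          # name -> estimate
    se: dict
    tvalues: dict
    pvalues: dict
    r_squared: float
    n: int

    @property
    def slope(self) -> float:
        return next(v for k, v in self.params.items() if k != "intercept")


@dataclass(frozen=True)
class MixedModelResult:
    params: dict
    se: dict
    tvalues: dict
    pvalues: dict
    var_group: float
    var_resid: float
    n_groups: int
    n: int
    loglik_reml: float
    df: float
    df_method: str = "residual"
    method: str = "REML"
    reduced_to_ols: bool = False


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    mean_diff: float


@dataclass(frozen=True)
class RepeatabilityResult:
    R: float
    ci_low: float
    ci_high: float
    p: float
    var_individual: float
    var_resid: float
    n_individuals: int
    n_measurements: int


def midparent_regression(brood_means, midparent) -> RegressionResult:
    """OLS of brood-mean offspring trait on the mid-parent value.

    Under purely additive inheritance the expected slope is the
    narrow-sense heritability h2.  Two-sided p-values use the t
    distribution with n - 2 degrees of freedom.
    """
    y = np.asarray(brood_means, dtype=float)
    x = np.asarray(midparent, dtype=float)
    if y.size != x.size:
        raise ValueError("brood_means and midparent must have equal length")
    if y.size < 3:
        raise ValueError("need at least 3 broods")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(x))):
        raise ValueError("nonfinite values in regression inputs")
    if np.var(x) == 0:
        raise ValueError("zero variance in mid-parent values")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    names = ["intercept", "midparent"]
    return RegressionResult(
        params=dict(zip(names, fit.params)),
        se=dict(zip(names, fit.bse)),
        tvalues=dict(zip(names, fit.tvalues)),
        pvalues=dict(zip(names, fit.pvalues)),
        r_squared=float(fit.rsquared),
        n=int(y.size),
    )


def _reml_profile(y, X, groups):
    """Profiled restricted log-likelihood machinery for a single random
    intercept.  H(gamma) = I + gamma Z Z' is handled per group via
    Sherman-Morrison, so everything is exact and fast at any group count."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    codes, levels = pd.factorize(np.asarray(groups))
    g = len(levels)
    by_group = [np.flatnonzero(codes == k) for k in range(g)]

    def components(gamma):
        # X'H^-1X, X'H^-1y, y'H^-1y, log|H| via per-group Sherman-Morrison
        XtHX = X.T @ X
        XtHy = X.T @ y
        ytHy = y @ y
        logdet = 0.0
        for rows in by_group:
            m = rows.size
            c = gamma / (1.0 + gamma * m)
            sx = X[rows].sum(axis=0)
            sy = y[rows].sum()
            XtHX -= c * np.outer(sx, sx)
            XtHy -= c * sx * sy
            ytHy -= c * sy * sy
            logdet += math.log1p(gamma * m)
        return XtHX, XtHy, ytHy, logdet

    def profile(gamma):
        XtHX, XtHy, ytHy, logdet = components(gamma)
        sign, logdet_xx = np.linalg.slogdet(XtHX)
        if sign <= 0:
            raise ValueError("singular fixed-effect design")
        beta = np.linalg.solve(XtHX, XtHy)
        rss = ytHy - XtHy @ beta  # y'Py up to the 1/sigma2_e factor
        rss = max(float(rss), 1e-300)
        s2e = rss / (n - p)
        ll = -0.5 * (logdet + logdet_xx + (n - p) * (1.0 + math.log(2 * math.pi * s2e)))
        return ll, beta, s2e, XtHX

    def score(gamma):
        """d(-2 l_R)/dgamma — its positive-side root is the REML optimum.

        All pieces (H^-1 X, H^-1 y, group sums) come from the same per-group
        Sherman-Morrison identities, so the score is exact and brentq can
        drive it to machine precision where derivative-free search stalls at
        ~sqrt(eps)."""
        shrink = [gamma / (1.0 + gamma * rows.size) for rows in by_group]
        HiX = X.copy()
        Hiy = y.copy()
        for rows, c in zip(by_group, shrink):
            HiX[rows] -= c * X[rows].sum(axis=0)
            Hiy[rows] -= c * y[rows].sum()
        XtHX = X.T @ HiX
        XtHy = X.T @ Hiy
        beta = np.linalg.solve(XtHX, XtHy)
        Py = Hiy - HiX @ beta
        ytPy = float(y @ Py)
        ZtPy = np.array([Py[rows].sum() for rows in by_group])
        ZtHiX = np.array([HiX[rows].sum(axis=0) for rows in by_group])
        tr_term = float(np.trace(np.linalg.solve(XtHX, ZtHiX.T @ ZtHiX)))
        dlogdet = sum(rows.size / (1.0 + gamma * rows.size)
                      for rows in by_group)
        return dlogdet - tr_term - (n - p) * float(ZtPy @ ZtPy) / ytPy

    return profile, score, n, p, g, by_group, (codes, levels)


def lmm_random_intercept(response, fixed, groups) -> MixedModelResult:
    """Random-intercept linear mixed model estimated by REML.

    The variance-ratio gamma = var_group / var_resid is profiled out of the
    restricted likelihood and maximized by bounded one-dimensional search;
    fixed effects are the GLS estimates at the optimum.  ``fixed`` is a
    DataFrame / 2-D array of predictors (an intercept is added) or None
    for an intercept-only model.  Fixed-effect t-tests use residual-style
    degrees of freedom n - p - (g - 1), recorded in ``df_method``; for
    reproducing estimates this choice is immaterial.
    """
    y = np.asarray(response, dtype=float)
    n = y.size
    if fixed is None:
        X = np.ones((n, 1))
        names = ["intercept"]
    else:
        if isinstance(fixed, pd.DataFrame):
            names = ["intercept"] + [str(c) for c in fixed.columns]
            X = np.column_stack([np.ones(n), fixed.to_numpy(dtype=float)])
        else:
            fx = np.atleast_2d(np.asarray(fixed, dtype=float))
            if fx.shape[0] != n:
                fx = fx.T
            names = ["intercept"] + [f"x{k + 1}" for k in range(fx.shape[1])]
            X = np.column_stack([np.ones(n), fx])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular fixed-effect design")

    profile, score, n, p, g, by_group, _ = _reml_profile(y, X, groups)
    if n <= p:
        raise ValueError("more fixed-effect parameters than observations")

    all_singletons = all(len(rows) == 1 for rows in by_group)
    if g < 2 or all_singletons:
        gamma_hat = 0.0
        reduced = True
    else:
        reduced = False
        if score(0.0) >= 0.0:
            gamma_hat = 0.0  # boundary: no between-group variance
        else:
            lo, hi = 0.0, 1.0
            while score(hi) < 0.0 and hi < 1e12:
                lo, hi = hi, hi * 8.0
            if score(hi) < 0.0:
                gamma_hat = hi  # pathological: variance ratio off to infinity
            else:
                gamma_hat = float(optimize.brentq(score, lo, hi,
                                                  xtol=1e-14, rtol=8.9e-16))
        if profile(0.0)[0] >= profile(gamma_hat)[0]:
            gamma_hat = 0.0

    ll, beta, s2e, XtHX = profile(gamma_hat)
    s2g = gamma_hat * s2e
    cov_beta = s2e * np.linalg.inv(XtHX)
    se = np.sqrt(np.diag(cov_beta))
    tvals = beta / se
    df = n - p - (g - 1 if s2g > 0 else 0)
    df = max(df, 1)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    return MixedModelResult(
        params=dict(zip(names, beta)),
        se=dict(zip(names, se)),
        tvalues=dict(zip(names, tvals)),
        pvalues=dict(zip(names, pvals)),
        var_group=float(s2g),
        var_resid=float(s2e),
        n_groups=int(g),
        n=int(n),
        loglik_reml=float(ll),
        df=float(df),
        reduced_to_ols=bool(reduced or s2g == 0.0),
    )


def paired_t_test(before, after) -> PairedTResult:
    """Classical paired t-test on after - before differences (df = n - 1).

    Conventions for degenerate inputs: if every difference equals the same
    nonzero constant, t is +/-inf and p = 0; if all differences are zero,
    t = 0 and p = 1.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if a.size != b.size:
        raise ValueError("paired vectors must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if md == 0.0:
            return PairedTResult(t=0.0, df=n - 1, p=1.0, mean_diff=0.0)
        return PairedTResult(t=math.copysign(math.inf, md), df=n - 1, p=0.0,
                             mean_diff=md)
    t = md / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return PairedTResult(t=float(t), df=n - 1, p=float(p), mean_diff=md)


def repeatability(values, individuals, n_boot: int = 500,
                  seed: int = 0, prob: float = 0.95) -> RepeatabilityResult:
    """Within-individual repeatability R (intraclass correlation).

    R = var_individual / (var_individual + var_resid) from the
    intercept-only random-intercept REML fit.  The confidence interval is a
    parametric bootstrap (simulate from the fitted model, refit, percentile
    interval); the p-value is a restricted likelihood-ratio test against
    the no-individual-effect model using the boundary-corrected 0.5 chi2(1)
    null mixture.
    """
    y = np.asarray(values, dtype=float)
    labels = np.asarray(individuals)
    codes, levels = pd.factorize(labels)
    counts = np.bincount(codes)
    if not np.any(counts >= 2):
        raise ValueError("repeatability needs repeated measurements")
    if (counts >= 2).sum() < 2:
        raise ValueError("need at least 2 individuals with >= 2 measurements")

    fit = lmm_random_intercept(y, None, labels)
    tot = fit.var_group + fit.var_resid
    R = fit.var_group / tot if tot > 0 else 0.0

    profile = _reml_profile(y, np.ones((y.size, 1)), labels)[0]
    g = fit.n_groups
    ll0 = profile(0.0)[0]
    lr = max(0.0, 2.0 * (fit.loglik_reml - ll0))
    pval = 0.5 * stats.chi2.sf(lr, 1) if lr > 0 else 1.0

    rng = np.random.default_rng(seed)
    mu = fit.params["intercept"]
    boots = []
    for _ in range(n_boot):
        u = rng.normal(0.0, math.sqrt(fit.var_group), g)
        sim = mu + u[codes] + rng.normal(0.0, math.sqrt(fit.var_resid), y.size)
        bf = lmm_random_intercept(sim, None, labels)
        bt = bf.var_group + bf.var_resid
        boots.append(bf.var_group / bt if bt > 0 else 0.0)
    alpha = 1.0 - prob
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2]) if boots else (R, R)
    return RepeatabilityResult(
        R=float(np.clip(R, 0, 1)),
        ci_low=float(np.clip(lo, 0, 1)),
        ci_high=float(np.clip(hi, 0, 1)),
        p=float(pval),
        var_individual=float(fit.var_group),
        var_resid=float(fit.var_resid),
        n_individuals=int(g),
        n_measurements=int(y.size),
    )
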