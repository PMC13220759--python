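"""Truncated negative-binomial (TNB) regression for baseline burden modeling.

The weighted interaction burden Y of a background gene pair is modeled as

    Y ~ TNB(mu, theta, t),   support {t+1, t+2, ...}

i.e. a negative binomial with mean ``mu`` and dispersion ``theta``
(variance mu + mu^2/theta) renormalized over values above the truncation
point ``t``; ``t = -1`` recovers the untruncated NB. The truncation absorbs
the inflated mass of pairs with very low burden that a plain NB fits badly.

The log link regresses ln(mu) on the products of six per-gene genomic
features and, optionally, the pair's burden observed in controls:

    ln(mu_ij) = beta0 + sum_l beta_l X_l,i X_l,j + beta7 X7_ij

Coefficients and theta are estimated jointly by maximum likelihood
(L-BFGS-B on (beta, log theta) with an analytic gradient; predictors are
standardized internally for conditioning and coefficients reported on the
original scale). Enrichment of a pair is tested through the standardized
deviance residual d', with one-sided p = 1 - Phi(d').
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TNBModel",
    "BackgroundTooSmall",
    "tnb_pmf",
    "fit_tnb",
    "predict_mu",
    "deviance_residuals",
    "truncated_mean",
    "standardize_residuals",
    "apply_residual_scale",
    "pvalues_from_dstd",
    "deviance_pvalue",
    "mlfc",
    "bh_fdr",
]

#: minimum number of background pairs for an accepted fit; smaller
#: backgrounds risk overfitting the baseline model.
MIN_BACKGROUND = 5000

_ETA_CLIP = 30.0


class BackgroundTooSmall(RuntimeError):
    """Raised when fewer eligible pairs remain than the overfitting guard allows."""


@dataclass
class TNBModel:
    """Fitted truncated negative-binomial regression.

    beta: coefficients on the original predictor scale, intercept first.
    theta: NB dispersion (variance mu + mu^2/theta).
    t: truncation point; b: score bin length the burdens were computed at.
    residual_scale: (mean, sd) used to standardize deviance residuals,
    estimated on the background fit set.
    """

    beta: np.ndarray
    theta: float
    t: int
    b: float | None
    loglik: float
    converged: bool
    n_pairs_fit: int
    beta_se: np.ndarray | None = None
    residual_scale: tuple = (0.0, 1.0, 0.0, 0.0, 1.0)
    eta_range: tuple[float, float] | None = None
    message: str = ""
    predictor_names: list[str] = field(default_factory=list)

    def summary(self) -> str:
        names = self.predictor_names or [
            f"x{i}" for i in range(len(self.beta) - 1)
        ]
        lines = [
            f"TNB regression: t={self.t} b={self.b} theta={self.theta:.6g}",
            f"loglik={self.loglik:.4f} n_fit={self.n_pairs_fit} "
            f"converged={self.converged}",
        ]
        se = self.beta_se if self.beta_se is not None else [np.nan] * len(self.beta)
        for name, bval, s in zip(["intercept"] + list(names), self.beta, se):
            lines.append(f"  {name:>12s}  beta={bval: .6g}  se={s:.4g}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# distribution


def _nb_logpmf(y, mu, theta):
    """NB log pmf, mean/dispersion parameterization (vectorized)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return (
        special.gammaln(y + theta)
        - special.gammaln(theta)
        - special.gammaln(y + 1.0)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))
    )


def _trunc_logsurv(mu, theta, t: int):
    """log P(Y > t) for the parent NB; t = -1 gives 0.

    Uses scipy's log survival function: forming 1 - cdf directly cancels
    catastrophically when mu is tiny and the cdf rounds to 1.
    """
    mu = np.asarray(mu, dtype=float)
    if t < 0:
        return np.zeros_like(mu)
    p = theta / (theta + mu)
    return stats.nbinom.logsf(t, theta, p)


def tnb_pmf(y, mu, theta, t: int):
    """Probability mass of the truncated NB at integer(s) ``y``.

    Zero below or at the truncation point; ``t = -1`` is the plain NB.
    Uses scipy's nbinom for the parent distribution.
    """
    if not (np.all(np.isfinite(mu)) and np.isfinite(theta)):
        raise ValueError("mu and theta must be finite")
    if np.any(np.asarray(mu) <= 0) or theta <= 0:
        raise ValueError("mu and theta must be positive")
    y = np.asarray(y)
    p = theta / (theta + np.asarray(mu, dtype=float))
    parent = stats.nbinom(theta, p)
    pm = parent.pmf(y)
    if t >= 0:
        surv = 1.0 - parent.cdf(t)
        pm = np.where(y > t, pm / surv, 0.0)
    if pm.ndim == 0:
        return float(pm)
    return pm


def truncated_mean(mu, theta, t: int):
    """Mean of the TNB: E[Y | Y > t].

    The moment identity (mu - sum_{k<=t} k pmf(k)) / P(Y > t) cancels
    catastrophically for small mu (the numerator is orders of magnitude
    below pmf round-off), so small means use a self-normalized partial sum
    over the truncated support instead.
    """
    mu = np.asarray(mu, dtype=float)
    if t < 0:
        return mu
    scalar = mu.ndim == 0
    mu = np.atleast_1d(mu)
    p = theta / (theta + mu)
    parent = stats.nbinom(theta, p)
    surv = parent.sf(t)
    low = sum(k * parent.pmf(k) for k in range(1, t + 1))
    out = (mu - low) / np.maximum(surv, 1e-300)

    small = mu < 0.5
    if small.any():
        ms = mu[small]
        ps = theta / (theta + ms)
        ks = np.arange(t + 1, t + 60)[:, None]
        pk = stats.nbinom.pmf(ks, theta, ps[None, :])
        total = pk.sum(axis=0)
        out[small] = (ks * pk).sum(axis=0) / np.maximum(total, 1e-300)
    return out[0] if scalar else out


# ---------------------------------------------------------------------------
# likelihood with analytic gradient (internal, standardized design)


def _negll_and_grad(params, Z, y, t, gammaln_y1):
    """Mean negative TNB log-likelihood and gradient on (b0, gamma, log theta).

    Z is the standardized design without intercept; closed-form truncation
    terms cover t in {0, 1, 2} (higher t falls back to the generic sum).
    """
    n, d = Z.shape
    b0 = params[0]
    gamma = params[1 : 1 + d]
    theta = np.exp(params[-1])
    eta = np.clip(b0 + Z @ gamma, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    tm = theta + mu
    logp = np.log(theta / tm)
    logq = eta - np.log(tm)

    ll = (
        special.gammaln(y + theta)
        - special.gammaln(theta)
        - gammaln_y1
        + theta * logp
        + y * logq
    )
    dll_deta = theta * (y - mu) / tm
    dll_dth = (
        special.digamma(y + theta)
        - special.digamma(theta)
        + logp
        + (mu - y) / tm
    )

    if t >= 0:
        q = mu / tm
        pmf = [np.exp(theta * logp)]  # k = 0
        psi_diff = [0.0]
        coef = 1.0
        for k in range(1, t + 1):
            coef *= (theta + k - 1.0) / k
            pmf.append(coef * pmf[0] * q**k)
            psi_diff.append(psi_diff[-1] + 1.0 / (theta + k - 1.0))
        cdf = np.sum(pmf, axis=0)
        surv = np.maximum(1.0 - cdf, 1e-300)
        ll = ll - np.log(surv)
        # d pmf(k)/d eta = pmf(k) * theta (k - mu) / tm
        num_eta = sum(pmf[k] * theta * (k - mu) / tm for k in range(t + 1))
        num_th = sum(
            pmf[k] * (psi_diff[k] + logp + (mu - k) / tm) for k in range(t + 1)
        )
        dll_deta = dll_deta + num_eta / surv
        dll_dth = dll_dth + num_th / surv

    nll = -float(np.sum(ll)) / n
    g = np.empty(d + 2)
    g[0] = -float(np.sum(dll_deta)) / n
    g[1 : 1 + d] = -(Z.T @ dll_deta) / n
    g[-1] = -float(np.sum(dll_dth)) * theta / n
    return nll, g


def _loglik_obs(y, mu, theta, t):
    """Per-observation TNB log-likelihood (original scale)."""
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-12)
    return _nb_logpmf(y, mu, theta) - _trunc_logsurv(mu, theta, t)


def fit_tnb(
    y,
    X,
    t: int,
    b: float | None = None,
    min_pairs: int = MIN_BACKGROUND,
    init: TNBModel | None = None,
    max_iter: int = 500,
    gtol: float = 1e-6,
    compute_se: bool = False,
    predictor_names=None,
) -> TNBModel:
    """Fit the TNB regression by maximum likelihood.

    ``y``: burdens of the background pairs (all must exceed ``t`` — callers
    filter to the support first); ``X``: predictor matrix without intercept
    column (raw feature products, optionally the control burden). Raises
    :class:`BackgroundTooSmall` when fewer than ``min_pairs`` observations
    are available — fitting a flexible baseline on a small background would
    overfit and mask true signals.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.any(y <= t):
        raise ValueError("all fitted burdens must lie above the truncation point")
    n, d = X.shape
    if n < min_pairs:
        raise BackgroundTooSmall(
            f"{n} eligible pairs < required minimum {min_pairs}"
        )

    m = X.mean(axis=0)
    s = X.std(axis=0)
    s = np.where(s > 0, s, 1.0)
    Z = (X - m) / s
    gammaln_y1 = special.gammaln(y + 1.0)

    if init is not None and len(init.beta) == d + 1:
        beta0 = np.asarray(init.beta, dtype=float)
        x0 = np.empty(d + 2)
        x0[1 : 1 + d] = beta0[1:] * s
        x0[0] = beta0[0] + float(beta0[1:] @ m)
        x0[-1] = np.log(init.theta)
    else:
        # Poisson-flavored start: least squares of log y on Z, moment theta
        A = np.column_stack([np.ones(n), Z])
        coef, *_ = np.linalg.lstsq(A, np.log(np.maximum(y, 0.5)), rcond=None)
        mu0 = np.exp(np.clip(A @ coef, -_ETA_CLIP, _ETA_CLIP))
        excess = np.mean(((y - mu0) ** 2 - mu0) / np.maximum(mu0**2, 1e-12))
        theta0 = 1.0 / excess if excess > 1e-4 else 1e4
        theta0 = float(np.clip(theta0, 0.05, 1e4))
        x0 = np.concatenate([coef, [np.log(theta0)]])

    bounds = [(None, None)] * (d + 1) + [(np.log(1e-4), np.log(1e7))]
    res = optimize.minimize(
        _negll_and_grad,
        x0,
        args=(Z, y, t, gammaln_y1),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12},
    )

    gamma = res.x[1 : 1 + d]
    beta = np.empty(d + 1)
    beta[1:] = gamma / s
    beta[0] = res.x[0] - float((gamma * m / s).sum())
    theta = float(np.exp(res.x[-1]))
    # trusted prediction range: central 99.8% of fitted linear predictors
    # (a handful of extreme fit points must not define how far the
    # exponential link may extrapolate)
    eta_fit = np.clip(res.x[0] + Z @ gamma, -_ETA_CLIP, _ETA_CLIP)
    eta_range = (
        float(np.quantile(eta_fit, 0.001)),
        float(np.quantile(eta_fit, 0.999)),
    )

    beta_se = None
    if compute_se:
        beta_se = _beta_se(res.x, Z, y, t, gammaln_y1, m, s, n)

    return TNBModel(
        beta=beta,
        theta=theta,
        t=t,
        b=b,
        loglik=-res.fun * n,
        converged=bool(res.success),
        n_pairs_fit=n,
        beta_se=beta_se,
        eta_range=eta_range,
        message=str(res.message),
        predictor_names=list(predictor_names) if predictor_names else [],
    )


def _beta_se(xopt, Z, y, t, gammaln_y1, m, s, n):
    """Standard errors from the numerically differentiated observed information."""
    k = len(xopt)
    H = np.zeros((k, k))
    eps = 1e-5
    for i in range(k):
        xp = xopt.copy()
        xm = xopt.copy()
        h = eps * max(1.0, abs(xopt[i]))
        xp[i] += h
        xm[i] -= h
        _, gp = _negll_and_grad(xp, Z, y, t, gammaln_y1)
        _, gm = _negll_and_grad(xm, Z, y, t, gammaln_y1)
        H[i] = (gp - gm) / (2 * h)
    H = (H + H.T) / 2 * n  # observed information of the total loglik
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    d = len(s)
    # Jacobian of (b0, gamma) -> (beta0, beta) on the original scale
    J = np.zeros((d + 1, d + 1))
    J[0, 0] = 1.0
    J[0, 1:] = -m / s
    J[1:, 1:] = np.diag(1.0 / s)
    cov_b = J @ cov[: d + 1, : d + 1] @ J.T
    var = np.diag(cov_b)
    return np.sqrt(np.where(var > 0, var, np.nan))


def predict_mu(model: TNBModel, X) -> np.ndarray:
    """Expected parent-NB baseline burden exp(beta0 + X beta).

    The linear predictor is clipped to the range spanned by the background
    fit set: the log-linear form is an approximation trusted only over the
    predictor combinations it was estimated on, and letting it extrapolate
    exponentially beyond them produces absurd baselines for extreme pairs.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    eta = model.beta[0] + X @ model.beta[1:]
    lo, hi = model.eta_range if model.eta_range is not None else (-_ETA_CLIP, _ETA_CLIP)
    return np.exp(np.clip(eta, lo, hi))


# ---------------------------------------------------------------------------
# residuals and testing


def deviance_residuals(y, mu, theta, t: int) -> np.ndarray:
    """Signed deviance residuals under the TNB likelihood.

    d = sign(y - mu_T) sqrt(2 [l(y; y) - l(mu; y)]), mu_T the truncated mean.
    Only meaningful for y > t; entries at or below t return NaN.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    ok = y > t
    d = np.full(y.shape, np.nan)
    if not np.any(ok):
        return d
    yk, mk = y[ok], mu[ok]
    ll_sat = _loglik_obs(yk, yk, theta, t)
    ll_fit = _loglik_obs(yk, mk, theta, t)
    dev = np.maximum(2.0 * (ll_sat - ll_fit), 0.0)
    sign = np.sign(yk - truncated_mean(mk, theta, t))
    sign = np.where(sign == 0, 1.0, sign)
    d[ok] = sign * np.sqrt(dev)
    return d


def standardize_residuals(d, background_mask):
    """Standardize deviance residuals over the background fit set.

    Beyond plain z-scoring, a one-term Cornish-Fisher adjustment removes the
    skewness of the background residual distribution (count deviances are
    right-skewed at low means), so that the standard-normal tail used for
    the p-value matches the background tail. The quadratic term is saturated
    at z = 3/skew to keep the map monotone for extreme (signal) residuals.
    Returns (d_std, scale) where ``scale`` reapplies the exact transform to
    new residuals; the standardized background has mean 0 and variance 1 by
    construction.
    """
    d = np.asarray(d, dtype=float)
    bg = d[np.asarray(background_mask)]
    bg = bg[np.isfinite(bg)]
    mean = float(bg.mean())
    sd = float(bg.std())
    if not np.isfinite(sd) or sd <= 0:
        sd = 1.0
    z_bg = (bg - mean) / sd
    gamma = float(np.mean(z_bg**3))
    adj_bg = _cf_adjust(z_bg, gamma)
    mean2 = float(adj_bg.mean())
    sd2 = float(adj_bg.std())
    if not np.isfinite(sd2) or sd2 <= 0:
        sd2 = 1.0
    scale = (mean, sd, gamma, mean2, sd2)
    return apply_residual_scale(d, scale), scale


def _cf_adjust(z, gamma):
    """One-term Cornish-Fisher skewness removal, saturated for monotonicity."""
    if abs(gamma) < 1e-12:
        return z
    cap = 3.0 / abs(gamma)
    zc = np.clip(z, -cap, cap)
    return z - (gamma / 6.0) * (zc**2 - 1.0)


def apply_residual_scale(d, scale):
    """Apply a stored standardization (from :func:`standardize_residuals`)."""
    mean, sd, gamma, mean2, sd2 = scale
    z = (np.asarray(d, dtype=float) - mean) / sd
    return (_cf_adjust(z, gamma) - mean2) / sd2


def pvalues_from_dstd(d_std) -> np.ndarray:
    """One-sided upper-tail p = 1 - Phi(d'); NaN residuals (burden within the
    truncated region, no enrichment evidence possible) map to p = 1."""
    d_std = np.asarray(d_std, dtype=float)
    p = stats.norm.sf(d_std)
    return np.where(np.isfinite(d_std), p, 1.0)


def deviance_pvalue(y, mu, model: TNBModel):
    """Standardized deviance residual d' and one-sided p-value for burdens
    under a fitted model (uses the model's stored standardization)."""
    d = deviance_residuals(y, mu, model.theta, model.t)
    d_std = apply_residual_scale(d, model.residual_scale)
    return d_std, pvalues_from_dstd(d_std)


def mlfc(p_values) -> float:
    """Mean log2 fold change of ordered p-values from uniform order statistics.

    MLFC = mean_r |log2( p_(r) / (r/(n+1)) )|; 0 means perfectly calibrated
    background p-values.
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    if p.size < 2:
        raise ValueError("need at least 2 p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    tiny = np.finfo(float).tiny
    p = np.maximum(p, tiny)
    n = p.size
    expected = np.arange(1, n + 1) / (n + 1.0)
    return float(np.mean(np.abs(np.log2(p / expected))))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
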