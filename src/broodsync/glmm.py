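"""Maximum-likelihood binomial GLMM with a single random intercept.

The daily-intensity candidate models need AIC-comparable maximum-likelihood
fits of binomial mixed models (logit link, one grouping factor).  The
marginal likelihood integrates the random intercept out by *adaptive*
Gauss-Hermite quadrature — nodes recentred at each group's posterior mode
and rescaled by its curvature, the same approach as lme4's
``glmer(nAGQ=k)`` — and is maximised over the fixed effects and the log
random-effect standard deviation with BFGS.  Plain (non-adaptive)
quadrature is badly inaccurate here: a group contributes hundreds of
Bernoulli trials, so its integrand is far narrower than the prior.
Standard errors come from the numerically differentiated Hessian at the
optimum.

Deliberately minimal: one scalar random intercept, binomial
(successes, totals) response, dense design matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy.special import expit, gammaln, logsumexp


@dataclass
class GLMMResult:
    params: pd.Series        # fixed effects
    bse: pd.Series
    cov: np.ndarray          # covariance of (fixed effects, log re_sd)
    re_sd: float             # random-intercept standard deviation
    llf: float
    aic: float
    nobs: int
    n_groups: int
    converged: bool

    @property
    def k_params(self) -> int:
        return len(self.params) + 1

    def summary_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "re_sd": self.re_sd,
            "llf": self.llf,
            "aic": self.aic,
            "converged": self.converged,
        }


def _group_index(groups) -> tuple[np.ndarray, np.ndarray]:
    codes, _ = pd.factorize(np.asarray(groups))
    order = np.argsort(codes, kind="stable")
    starts = np.searchsorted(codes[order], np.arange(codes.max() + 1))
    return order, starts


def fit_binomial_glmm(
    successes,
    totals,
    exog: pd.DataFrame,
    groups,
    n_quad: int = 15,
    start_params: np.ndarray | None = None,
) -> GLMMResult:
    """Fit ``successes/totals ~ exog + (1 | groups)`` by ML (adaptive GH).

    ``exog`` should include an intercept column.  ``converged`` is False
    when the optimiser failed, so callers can drop the model from AIC
    rankings.
    """
    y = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    X = np.asarray(exog, dtype=float)
    names = list(exog.columns)
    order, starts = _group_index(groups)
    y, n, X = y[order], n[order], X[order]
    n_groups = len(starts)
    sizes = np.diff(np.append(starts, len(y)))

    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    log_w = np.log(weights) + nodes**2  # adaptive-GH weights
    binom_const = float(np.sum(
        gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)))

    def negll(theta: np.ndarray) -> float:
        beta, log_sd = theta[:-1], theta[-1]
        var = np.exp(2.0 * log_sd)
        eta = X @ beta
        # posterior mode of each group's random intercept (Newton)
        u = np.zeros(n_groups)
        for _ in range(50):
            p = expit(eta + np.repeat(u, sizes))
            grad = np.add.reduceat(y - n * p, starts) - u / var
            hess = -np.add.reduceat(n * p * (1.0 - p), starts) - 1.0 / var
            step = grad / hess
            u = u - step
            if np.max(np.abs(step)) < 1e-10:
                break
        p = expit(eta + np.repeat(u, sizes))
        h = np.add.reduceat(n * p * (1.0 - p), starts) + 1.0 / var
        s = np.sqrt(2.0 / h)  # per-group node scale
        ll_k = np.empty((n_groups, n_quad))
        for k, z in enumerate(nodes):
            uk = u + s * z
            lin = eta + np.repeat(uk, sizes)
            ll = y * lin - n * np.logaddexp(0.0, lin)
            ll_k[:, k] = np.add.reduceat(ll, starts) - 0.5 * uk * uk / var
        ll_g = (
            logsumexp(ll_k + log_w[None, :], axis=1)
            + np.log(s)
            - 0.5 * np.log(2.0 * np.pi * var)
        )
        return -(float(np.sum(ll_g)) + binom_const)

    if start_params is None:
        glm = sm.GLM(
            np.column_stack([y, n - y]), X, family=sm.families.Binomial()
        ).fit()
        start_params = np.concatenate([glm.params, [np.log(0.3)]])
    res = optimize.minimize(
        negll, start_params, method="BFGS",
        options={"gtol": 1e-6, "maxiter": 500},
    )
    theta = res.x
    llf = -float(res.fun)
    # BFGS often reports precision loss at the optimum; judge convergence
    # by the gradient norm relative to the log-likelihood scale
    grad_ok = np.max(np.abs(res.jac)) < max(0.5, 1e-3 * abs(llf))

    # observed-information standard errors via a central-difference Hessian
    k = len(theta)
    h = 1e-4 * np.maximum(1.0, np.abs(theta))
    H = np.empty((k, k))
    f0 = res.fun
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                H[i, i] = (negll(theta + ei) - 2 * f0 + negll(theta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    negll(theta + ei + ej) - negll(theta + ei - ej)
                    - negll(theta - ei + ej) + negll(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        bse = np.sqrt(np.clip(np.diag(cov)[:-1], 0.0, np.inf))
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
        bse = np.full(k - 1, np.nan)

    return GLMMResult(
        params=pd.Series(theta[:-1], index=names),
        bse=pd.Series(bse, index=names),
        cov=cov,
        re_sd=float(np.exp(theta[-1])),
        llf=llf,
        aic=2.0 * k - 2.0 * llf,
        nobs=len(y),
        n_groups=n_groups,
        converged=(bool(res.success) or grad_ok) and np.isfinite(llf),
    )
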