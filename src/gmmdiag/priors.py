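"""Log prior density for the mixture parameters.

The prior factorizes as

* Dirichlet(alpha0, ..., alpha0) on the class probabilities pi;
* half-normal or half-Cauchy with scale s on the random intercept and
  slope SDs of every class;
* LKJ(eta) on each 2x2 random-effect correlation matrix, i.e. density
  proportional to (1 - rho^2)^(eta - 1);
* independent zero-mean normals on the trajectory coefficients;
* half-normal on the shared residual SD.

Out-of-support parameter points return -inf rather than raising, so that
optimizers and samplers can reject them.
"""

from __future__ import annotations

import numpy as np
from scipy.special import betaln, gammaln

from .params import MixtureParams, PriorConfig

_LOG_2PI = np.log(2.0 * np.pi)


def _dirichlet_logpdf(pi: np.ndarray, alpha0: float) -> float:
    K = len(pi)
    if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-8:
        return -np.inf
    logB = K * gammaln(alpha0) - gammaln(K * alpha0)
    return float((alpha0 - 1.0) * np.sum(np.log(pi)) - logB)


def _halfnormal_logpdf(x: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return 0.5 * np.log(2.0 / np.pi) - np.log(scale) - 0.5 * (x / scale) ** 2


def _halfcauchy_logpdf(x: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return np.log(2.0 / np.pi) - np.log(scale) - np.log1p((x / scale) ** 2)


def _lkj2_logpdf(rho: float, eta: float) -> float:
    """Normalized LKJ density of the correlation of a 2x2 matrix.

    rho = 2v - 1 with v ~ Beta(eta, eta), so the density on (-1, 1) is
    (1 - rho^2)^(eta-1) / (2^(2 eta - 1) B(eta, eta)).
    """
    if not -1.0 < rho < 1.0:
        return -np.inf
    return ((eta - 1.0) * np.log1p(-rho**2)
            - (2.0 * eta - 1.0) * np.log(2.0) - betaln(eta, eta))


def _normal_logpdf(x: float, sd: float) -> float:
    return -0.5 * (_LOG_2PI + 2.0 * np.log(sd) + (x / sd) ** 2)


def log_prior(params: MixtureParams, prior: PriorConfig) -> float:
    """Sum of log prior densities; -inf outside the support."""
    lp = _dirichlet_logpdf(np.asarray(params.pi, dtype=float), prior.alpha0)
    if not np.isfinite(lp):
        return -np.inf
    half = (_halfnormal_logpdf if prior.sd_family == "half-normal"
            else _halfcauchy_logpdf)
    for cp in params.classes:
        lp += half(cp.sd_int, prior.sd_scale)
        lp += half(cp.sd_slope, prior.sd_scale)
        lp += _lkj2_logpdf(cp.corr, prior.lkj_shape)
        for b, s in zip(cp.beta, prior.beta_sds):
            lp += _normal_logpdf(b, s)
        if not np.isfinite(lp):
            return -np.inf
    lp += _halfnormal_logpdf(params.sigma_resid, prior.resid_sd_scale)
    return float(lp) if np.isfinite(lp) else -np.inf


def log_posterior(params: MixtureParams, prior: PriorConfig, data) -> float:
    """Unnormalized log posterior: mixture log-likelihood + log prior."""
    from .likelihood import mixture_loglik

    lp = log_prior(params, prior)
    if not np.isfinite(lp):
        return -np.inf
    return lp + mixture_loglik(params, data)
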