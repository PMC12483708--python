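"""Bijections between constrained mixture parameters and R^d.

Layout of the unconstrained vector theta (dimension 7K) for K classes:

    theta[0 : K-1]          additive log-ratio of pi (last class reference)
    theta[K-1 : K-1+3K]     trajectory coefficients, class-major
    next K                  log random-intercept SDs
    next K                  log random-slope SDs
    next K                  atanh correlations (Fisher z)
    last 1                  log residual SD

The same parameterization is used for HMC sampling, maximum-likelihood
optimization, and Uniform(-2, 2) random initialization.  The log
absolute Jacobian determinant of the constraining map is

    sum_k log pi_k + sum log sd + log(1 - rho^2) terms + log sigma,

added to the target so that densities specified on the constrained scale
sample correctly on R^d.
"""

from __future__ import annotations

import numpy as np

from .params import ClassParams, MixtureParams, PriorConfig

_SD_FLOOR = 1e-300


def dim(K: int) -> int:
    return 7 * K


def _softmax_with_ref(u: np.ndarray) -> np.ndarray:
    """pi = softmax([u, 0]) — additive log-ratio inverse."""
    a = np.concatenate([u, [0.0]])
    a -= a.max()
    e = np.exp(a)
    return e / e.sum()


def unconstrain(params: MixtureParams) -> np.ndarray:
    K = params.n_classes
    pi = np.clip(params.pi, 1e-12, None)
    u_pi = np.log(pi[:-1]) - np.log(pi[-1])
    betas = np.concatenate([cp.beta for cp in params.classes])
    log_si = np.log([max(cp.sd_int, _SD_FLOOR) for cp in params.classes])
    log_ss = np.log([max(cp.sd_slope, _SD_FLOOR) for cp in params.classes])
    z_rho = np.arctanh(np.clip([cp.corr for cp in params.classes],
                               -1 + 1e-12, 1 - 1e-12))
    return np.concatenate([u_pi, betas, log_si, log_ss, z_rho,
                           [np.log(max(params.sigma_resid, _SD_FLOOR))]])


def _split(theta: np.ndarray, K: int):
    if theta.shape != (dim(K),):
        raise ValueError(f"theta must have shape ({dim(K)},)")
    i = K - 1
    u_pi = theta[:i]
    betas = theta[i:i + 3 * K].reshape(K, 3)
    i += 3 * K
    log_si = theta[i:i + K]
    i += K
    log_ss = theta[i:i + K]
    i += K
    z_rho = theta[i:i + K]
    log_sigma = theta[-1]
    return u_pi, betas, log_si, log_ss, z_rho, log_sigma


def constrain(theta: np.ndarray, K: int) -> MixtureParams:
    u_pi, betas, log_si, log_ss, z_rho, log_sigma = _split(np.asarray(theta, float), K)
    pi = _softmax_with_ref(u_pi)
    classes = tuple(
        ClassParams(beta0=b[0], beta1=b[1], beta2=b[2],
                    sd_int=float(np.exp(ls1)), sd_slope=float(np.exp(ls2)),
                    corr=float(np.tanh(z)))
        for b, ls1, ls2, z in zip(betas, log_si, log_ss, z_rho))
    return MixtureParams(pi=pi, classes=classes,
                         sigma_resid=float(np.exp(log_sigma)))


def log_jacobian(theta: np.ndarray, K: int) -> float:
    """log |det d(constrained)/d(theta)|."""
    u_pi, _, log_si, log_ss, z_rho, log_sigma = _split(np.asarray(theta, float), K)
    pi = _softmax_with_ref(u_pi)
    rho = np.tanh(z_rho)
    return float(np.sum(np.log(pi)) + np.sum(log_si) + np.sum(log_ss)
                 + np.sum(np.log1p(-rho**2)) + log_sigma)


def initialize_unconstrained(K: int, seed: int) -> np.ndarray:
    """Stan-style random initialization: Uniform(-2, 2) per coordinate."""
    rng = np.random.default_rng(seed)
    return rng.uniform(-2.0, 2.0, size=dim(K))


# ----------------------------------------------------------------------
# log posterior and gradient on the unconstrained scale

def logpost_and_grad(theta: np.ndarray, data, prior: PriorConfig, K: int,
                     include_likelihood: bool = True,
                     include_prior: bool = True):
    """Unnormalized log posterior and its gradient in theta.

    The target is  loglik + logprior + log|Jacobian|  so that the prior
    specified on the constrained scale is sampled correctly.  Setting
    ``include_prior=False`` gives the pure marginal likelihood (plus no
    Jacobian), used by the maximum-likelihood optimizer.
    """
    from .likelihood import loglik_and_grads

    theta = np.asarray(theta, dtype=float)
    u_pi, betas, log_si, log_ss, z_rho, log_sigma = _split(theta, K)
    pi = _softmax_with_ref(u_pi)
    sd_int = np.exp(log_si)
    sd_slope = np.exp(log_ss)
    rho = np.tanh(z_rho)
    sigma = np.exp(log_sigma)
    params = constrain(theta, K)

    lp = 0.0
    grad = np.zeros_like(theta)
    g_upi = np.zeros(K - 1)
    g_beta = np.zeros((K, 3))
    g_lsi = np.zeros(K)
    g_lss = np.zeros(K)
    g_z = np.zeros(K)
    g_lsigma = 0.0

    n = data.n_subjects if data is not None else 0

    if include_likelihood:
        ll, sum_w, g = loglik_and_grads(params, data)
        lp += ll
        # d loglik / d u_m = sum_j w_jm - n pi_m  (ALR chain rule)
        dl_dpi_full = sum_w - n * pi
        g_upi += dl_dpi_full[:-1] - 0.0  # reference class drops out
        # note: with softmax([u,0]), d/du_m = (sum_w - n pi)[m]; the
        # reference coordinate is fixed so only the first K-1 enter.
        g_beta += g["beta"]
        g_lsi += g["sd_int"] * sd_int
        g_lss += g["sd_slope"] * sd_slope
        g_z += g["corr"] * (1.0 - rho**2)
        g_lsigma += g["sigma"] * sigma

    if include_prior:
        from .priors import log_prior

        lp += log_prior(params, prior)
        if not np.isfinite(lp):
            return -np.inf, grad
        # Jacobian terms
        lp += float(np.sum(np.log(pi)) + np.sum(log_si) + np.sum(log_ss)
                    + np.sum(np.log1p(-rho**2)) + log_sigma)
        # Dirichlet + simplex Jacobian: alpha0 * sum_k log pi_k (+const)
        # d/du_m = alpha0 * (1 - K pi_m)
        g_upi += prior.alpha0 * (1.0 - K * pi[:-1])
        # trajectory coefficients
        bsd = np.asarray(prior.beta_sds, dtype=float)
        g_beta += -betas / bsd**2
        # SDs: prior on sd scale + d(log sd)/d(log sd) = 1 Jacobian term
        if prior.sd_family == "half-normal":
            dp_int = -sd_int / prior.sd_scale**2
            dp_slope = -sd_slope / prior.sd_scale**2
        else:  # half-Cauchy
            dp_int = -2.0 * sd_int / (prior.sd_scale**2 + sd_int**2)
            dp_slope = -2.0 * sd_slope / (prior.sd_scale**2 + sd_slope**2)
        g_lsi += dp_int * sd_int + 1.0
        g_lss += dp_slope * sd_slope + 1.0
        # LKJ(eta) + Jacobian: eta * log(1 - rho^2) -> d/dz = -2 eta rho
        g_z += -2.0 * prior.lkj_shape * rho
        # residual SD: half-normal prior + Jacobian
        g_lsigma += (-sigma / prior.resid_sd_scale**2) * sigma + 1.0

    i = K - 1
    grad[:i] = g_upi
    grad[i:i + 3 * K] = g_beta.ravel()
    i += 3 * K
    grad[i:i + K] = g_lsi
    i += K
    grad[i:i + K] = g_lss
    i += K
    grad[i:i + K] = g_z
    grad[-1] = g_lsigma
    return float(lp), grad
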