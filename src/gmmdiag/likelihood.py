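"""Marginal likelihood of the growth mixture model.

For class k, a subject's response vector is multivariate normal with mean
``X beta_k`` (X has columns 1, t, t^2) and covariance

    Sigma_k = Z Psi_k Z' + sigma^2 I,

where Z has columns (1, t) for the random intercept and slope.  The
mixture marginal log-likelihood is

    sum_j log sum_k pi_k f_k(y_j),

marginal over both the class indicator and the random effects, so no
discrete parameters or per-subject effects remain.  Gradient computations
(used by the HMC sampler and the ML optimizer) batch subjects that share
an observed time pattern: those subjects share one covariance factor.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .data import LongitudinalDataset
from .params import ClassParams, MixtureParams

_LOG_2PI = np.log(2.0 * np.pi)


def _logsumexp_rows(x: np.ndarray) -> np.ndarray:
    """Row-wise log-sum-exp, stable for -inf entries (skipped).

    Terms are accumulated in sorted order, so the result is bitwise
    invariant under permutations of the columns — the mixture
    log-likelihood is then *exactly* invariant under class relabeling,
    not merely up to rounding.
    """
    m = np.max(x, axis=1)
    safe_m = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(invalid="ignore"):
        shifted = np.sort(x - safe_m[:, None], axis=1)
        s = np.sum(np.exp(shifted), axis=1)
    return np.where(np.isfinite(m), safe_m + np.log(s), m)


def random_effects_design(times) -> np.ndarray:
    """Design matrix Z for the random effects: columns (1, t)."""
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("subject has no records (empty time vector)")
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite times")
    return np.column_stack([np.ones_like(t), t])


def fixed_effects_design(times) -> np.ndarray:
    """Design matrix X for the mean trajectory: columns (1, t, t^2)."""
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("subject has no records (empty time vector)")
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite times")
    return np.column_stack([np.ones_like(t), t, t**2])


def marginal_cov(class_params: ClassParams, sigma_resid: float, times) -> np.ndarray:
    """Marginal covariance Z Psi Z' + sigma^2 I for one subject.

    Symmetric by construction; positive definite whenever sigma_resid > 0.
    """
    Z = random_effects_design(times)
    psi = class_params.psi
    if not np.all(np.isfinite(psi)) or not np.isfinite(sigma_resid):
        raise ValueError("non-finite covariance parameters")
    cov = Z @ psi @ Z.T + sigma_resid**2 * np.eye(Z.shape[0])
    return 0.5 * (cov + cov.T)


def class_logdensity(y, times, class_params: ClassParams, sigma_resid: float) -> float:
    """Log marginal density of one subject's responses under one class."""
    y = np.asarray(y, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.shape != t.shape:
        raise ValueError("y and times must have the same length")
    X = fixed_effects_design(t)
    cov = marginal_cov(class_params, sigma_resid, t)
    r = y - X @ class_params.beta
    try:
        L = cho_factor(cov, lower=True)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "singular marginal covariance (sigma_resid = 0 with degenerate "
            "random-effect covariance?)") from e
    logdet = 2.0 * np.sum(np.log(np.diag(L[0])))
    quad = r @ cho_solve(L, r)
    return -0.5 * (len(y) * _LOG_2PI + logdet + quad)


# ----------------------------------------------------------------------
# vectorized internals

def _pattern_designs(data: LongitudinalDataset):
    """Cache (X, Z) per time pattern on the dataset object."""
    cache = getattr(data, "_design_cache", None)
    if cache is None:
        cache = [(fixed_effects_design(p.times), random_effects_design(p.times))
                 for p in data.patterns]
        data._design_cache = cache
    return cache


def _stack_class_covs(params: MixtureParams, Z: np.ndarray) -> np.ndarray:
    """(K, T, T) marginal covariances for one time pattern."""
    psis = np.stack([cp.psi for cp in params.classes])        # (K, 2, 2)
    covs = Z @ psis @ Z.T + params.sigma_resid**2 * np.eye(Z.shape[0])
    return 0.5 * (covs + covs.transpose(0, 2, 1))


def _class_loglik_matrix(params: MixtureParams, data: LongitudinalDataset):
    """Per-subject per-class log densities.

    Classes are batched through numpy's stacked linear algebra per time
    pattern (all subjects of a pattern share one covariance per class).

    Returns
    -------
    logf : (n, K) array in pattern-major subject order.
    info : list over patterns of (covs, A, R) with covs (K, T, T),
        A = Sigma^-1 r' of shape (K, T, n_p), residuals R (K, n_p, T);
        reused by the gradient pass.
    """
    K = params.n_classes
    designs = _pattern_designs(data)
    betas = np.stack([cp.beta for cp in params.classes])      # (K, 3)
    blocks = []
    info = []
    for p, (X, Z) in zip(data.patterns, designs):
        T = len(p.times)
        covs = _stack_class_covs(params, Z)
        if not np.all(np.isfinite(covs)):
            raise np.linalg.LinAlgError("non-finite marginal covariance")
        sign, logdet = np.linalg.slogdet(covs)                # (K,)
        if np.any(sign <= 0):
            k = int(np.nonzero(sign <= 0)[0][0])
            raise np.linalg.LinAlgError(
                f"singular marginal covariance for class {k}")
        means = betas @ X.T                                   # (K, T)
        R = p.responses[None, :, :] - means[:, None, :]       # (K, n_p, T)
        A = np.linalg.solve(covs, R.transpose(0, 2, 1))       # (K, T, n_p)
        quad = np.einsum("knt,ktn->nk", R, A)                 # (n_p, K)
        logf_p = -0.5 * (T * _LOG_2PI + logdet[None, :] + quad)
        blocks.append(logf_p)
        info.append((covs, A, R))
    return np.vstack(blocks), info


def _log_mix_weights(pi: np.ndarray) -> np.ndarray:
    """log pi with zero entries mapped to -inf (skipped in logsumexp)."""
    if np.all(pi <= 0):
        raise ValueError("all class probabilities are zero")
    with np.errstate(divide="ignore"):
        return np.where(pi > 0, np.log(np.clip(pi, 1e-300, None)), -np.inf)


def mixture_loglik(params: MixtureParams, data: LongitudinalDataset) -> float:
    """Mixture marginal log-likelihood sum_j log sum_k pi_k f_k(y_j).

    Uses a log-sum-exp that is stable when some pi_k are zero or some
    class densities underflow.
    """
    logf, _ = _class_loglik_matrix(params, data)
    logpi = _log_mix_weights(params.pi)
    return float(np.sum(_logsumexp_rows(logf + logpi)))


def classification_probs(params: MixtureParams, data: LongitudinalDataset) -> np.ndarray:
    """Posterior classification probabilities p_jk, rows on the simplex.

    Rows follow ``data.subjects`` order.
    """
    logf, _ = _class_loglik_matrix(params, data)
    logpi = _log_mix_weights(params.pi)
    logw = logf + logpi
    norm = _logsumexp_rows(logw)
    bad = np.nonzero(~np.isfinite(norm))[0]
    if bad.size:
        sid = data.subject_order[bad[0]]
        raise FloatingPointError(
            f"all class densities underflow for subject {sid!r}")
    probs = np.exp(logw - norm[:, None])
    # pattern-major -> original subject order
    order = data.subject_order
    idx = {s: i for i, s in enumerate(order)}
    perm = [idx[s] for s in data.subjects]
    return probs[perm]


def loglik_and_grads(params: MixtureParams, data: LongitudinalDataset):
    """Log-likelihood with analytic gradients w.r.t. constrained parameters.

    Returns ``(loglik, sum_w, grads)`` where ``sum_w[k] = sum_j w_jk`` with
    w the per-subject classification weights, and ``grads`` is a dict with
    arrays ``beta`` (K,3), ``sd_int`` (K,), ``sd_slope`` (K,), ``corr``
    (K,) and scalar ``sigma``.  The pi gradient is left to the caller
    (clean form in unconstrained space: sum_w - n*pi).
    """
    K = params.n_classes
    logf, info = _class_loglik_matrix(params, data)
    logpi = _log_mix_weights(params.pi)
    logw = logf + logpi
    norm = _logsumexp_rows(logw)
    w = np.exp(logw - norm[:, None])                  # (n, K) pattern-major
    loglik = float(np.sum(norm))

    gbeta = np.zeros((K, 3))
    H_sum = np.zeros((K, 2, 2))
    trG_sum = 0.0
    sigma = params.sigma_resid
    designs = _pattern_designs(data)

    offset = 0
    for p, (X, Z), (covs, A, _R) in zip(data.patterns, designs, info):
        n_p = p.responses.shape[0]
        wv = w[offset:offset + n_p]                       # (n_p, K)
        offset += n_p
        sw = wv.sum(axis=0)                               # (K,)
        # d logf / d beta = X' Sigma^-1 r, weighted over subjects
        gbeta += np.einsum("ktn,nk->kt", A, wv) @ X
        # G_k = 0.5 * (sum_j w_jk a_j a_j' - sw_k Sigma_k^-1)
        prec = np.linalg.inv(covs)                        # (K, T, T)
        M = np.einsum("ktn,nk,ksn->kts", A, wv, A)
        G = 0.5 * (M - sw[:, None, None] * prec)
        H_sum += np.einsum("ti,kts,sj->kij", Z, G, Z)
        trG_sum += float(np.einsum("ktt->", G))

    s1 = np.array([cp.sd_int for cp in params.classes])
    s2 = np.array([cp.sd_slope for cp in params.classes])
    rho = np.array([cp.corr for cp in params.classes])
    grads = {
        "beta": gbeta,
        "sd_int": 2.0 * s1 * H_sum[:, 0, 0] + 2.0 * rho * s2 * H_sum[:, 0, 1],
        "sd_slope": 2.0 * s2 * H_sum[:, 1, 1] + 2.0 * rho * s1 * H_sum[:, 0, 1],
        "corr": 2.0 * s1 * s2 * H_sum[:, 0, 1],
        "sigma": 2.0 * sigma * trG_sum,
    }
    return loglik, w.sum(axis=0), grads
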