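"""Independent reference implementations used as test oracles.

Kept deliberately simple and separate from the package: a literal
transcription of the rank-normalized split R-hat recipe (Vehtari et al.,
2021) and a 2-D Gauss-Hermite quadrature evaluation of the class-specific
marginal density (integrating the conditional normal density over the
bivariate random effects).
"""

import numpy as np
from scipy.stats import norm, rankdata


def _split_chains(x: np.ndarray) -> np.ndarray:
    """Halve each chain: (m, n) -> (2m, n // 2)."""
    m, n = x.shape
    half = n // 2
    return np.vstack([x[:, :half], x[:, n - half:]])


def _z_scale(x: np.ndarray) -> np.ndarray:
    """Rank-normalize over all draws: z = Phi^-1((r - 3/8) / (S + 1/4))."""
    r = rankdata(x, method="average").reshape(x.shape)
    return norm.ppf((r - 3.0 / 8.0) / (x.size + 0.25))


def _basic_rhat(x: np.ndarray) -> float:
    """Classic potential scale reduction factor on (m, n) draws."""
    m, n = x.shape
    chain_means = x.mean(axis=1)
    chain_vars = x.var(axis=1, ddof=1)
    W = chain_vars.mean()
    B = n * chain_means.var(ddof=1)
    var_plus = (n - 1.0) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def reference_rank_rhat(x: np.ndarray) -> float:
    """Max of rank-normalized split R-hat and its folded variant."""
    split = _split_chains(np.asarray(x, dtype=float))
    bulk = _basic_rhat(_z_scale(split))
    folded = np.abs(split - np.median(split))
    tail = _basic_rhat(_z_scale(folded))
    return max(bulk, tail)


def gauss_hermite_class_logdensity(y, times, class_params, sigma_resid,
                                   n_nodes=150) -> float:
    """Class-specific marginal log density by 2-D quadrature over the
    random intercept and slope (zeta = sqrt(2) L u, u on the Gauss-Hermite
    grid, weight function exp(-|u|^2))."""
    y = np.asarray(y, dtype=float)
    t = np.asarray(times, dtype=float)
    X = np.column_stack([np.ones_like(t), t, t**2])
    Z = np.column_stack([np.ones_like(t), t])
    mean = X @ class_params.beta

    psi = class_params.psi
    L = np.linalg.cholesky(psi + 1e-300 * np.eye(2))
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    u1, u2 = np.meshgrid(nodes, nodes, indexing="ij")
    U = np.stack([u1.ravel(), u2.ravel()])              # (2, n^2)
    zetas = np.sqrt(2.0) * (L @ U)                      # (2, n^2)
    resid = (y - mean)[:, None] - Z @ zetas             # (T, n^2)
    log_cond = (-0.5 * np.sum(resid**2, axis=0) / sigma_resid**2
                - len(y) * np.log(np.sqrt(2 * np.pi) * sigma_resid))
    w = np.outer(weights, weights).ravel()
    m = log_cond.max()
    total = np.sum(w * np.exp(log_cond - m))
    return float(m + np.log(total) - np.log(np.pi))
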