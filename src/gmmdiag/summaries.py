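"""Within-class heterogeneity descriptors and predictive model comparison.

Heterogeneity of the latent trajectories within one class is driven by
the random-effect covariance Psi = [[psi11, psi12], [psi12, psi22]].
The descriptors below all follow from the trajectory deviation
``zeta1 + t * zeta2`` being normal with variance
``psi11 + 2 t psi12 + t^2 psi22``:

* ``trajectory_sd`` — SD of the latent trajectories at time t;
* ``midrange_band`` — central coverage band around the mean trajectory;
* ``slope_given_intercept`` — conditional mean of the random slope given
  the random intercept (a regression with coefficient psi12 / psi11);
* ``pct_change_deviation`` — expected percentage change between t0 and T
  of an individual's deviation from the class mean, conditional on the
  initial deviation;
* ``standardized_deviation_at_T`` — expected deviation at T in SD units
  for someone who starts a0 SDs from the mean;
* ``prob_positive_slope`` — probability of a positive random slope given
  a standardized initial deviation.

Model comparison uses WAIC (and PSIS-LOO via arviz) on the *mixed*
predictive distribution: the subject-level density marginal over both
class membership and random effects — never the conditional density.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .data import LongitudinalDataset
from .likelihood import _class_loglik_matrix, _log_mix_weights
from .params import ClassParams


# ----------------------------------------------------------------------
# heterogeneity

def trajectory_sd(class_params: ClassParams, t: float) -> float:
    """SD of the latent trajectories at time t:
    sqrt(psi11 + 2 t psi12 + t^2 psi22)."""
    psi = class_params.psi
    var = psi[0, 0] + 2.0 * t * psi[0, 1] + t**2 * psi[1, 1]
    if var < -1e-12:
        raise ValueError("negative trajectory variance; Psi not PSD")
    return float(np.sqrt(max(var, 0.0)))


def midrange_band(class_params: ClassParams, t: float,
                  coverage: float = 0.5) -> tuple[float, float]:
    """Central ``coverage`` band of the latent trajectories at time t."""
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must be in (0, 1)")
    m = float(class_params.mean(t))
    half = norm.ppf(0.5 * (1.0 + coverage)) * trajectory_sd(class_params, t)
    return m - half, m + half


def slope_given_intercept(class_params: ClassParams, zeta1: float) -> float:
    """Conditional expectation of the random slope given the intercept:
    (psi12 / psi11) * zeta1."""
    psi = class_params.psi
    if psi[0, 0] == 0:
        raise ZeroDivisionError("psi11 = 0: regression on intercept undefined")
    return float(psi[0, 1] / psi[0, 0] * zeta1)


def pct_change_deviation(class_params: ClassParams, t0: float, T: float) -> float:
    """Expected percentage change in deviation from the class mean
    between t0 and T, conditional on the initial deviation:
    100 * (T - t0) * psi12 / psi11.

    The implied deviation ratio is 1 + value / 100 (e.g. +147% means the
    deviation at T is about 2.5 times the deviation at t0).
    """
    psi = class_params.psi
    if psi[0, 0] == 0:
        raise ZeroDivisionError("psi11 = 0: percentage change undefined")
    return float(100.0 * (T - t0) * psi[0, 1] / psi[0, 0])


def standardized_deviation_at_T(class_params: ClassParams, a0: float,
                                t0: float, T: float) -> float:
    """Expected deviation at time T, in SD units at T, for an individual
    whose deviation at t0 is a0 SDs: a0 sd(t0) (1 + (T-t0) psi12/psi11) / sd(T)."""
    sd0 = trajectory_sd(class_params, t0)
    sdT = trajectory_sd(class_params, T)
    if sd0 == 0 or sdT == 0:
        raise ZeroDivisionError("zero trajectory SD at t0 or T")
    psi = class_params.psi
    return float(a0 * sd0 * (1.0 + (T - t0) * psi[0, 1] / psi[0, 0]) / sdT)


def prob_positive_slope(corr: float, a0: float) -> float:
    """P(random slope > 0 | standardized intercept deviation a0):
    Phi(rho a0 / sqrt(1 - rho^2))."""
    if abs(corr) >= 1.0:
        s = corr * a0
        if s == 0:
            raise ValueError("degenerate |rho| = 1 with a0 = 0")
        return 1.0 if s > 0 else 0.0
    return float(norm.cdf(corr * a0 / np.sqrt(1.0 - corr**2)))


def heterogeneity_summary(class_params: ClassParams, t0: float, T: float,
                          a0: float = 2.0, grid=None,
                          coverage: float = 0.5) -> dict:
    """All descriptors for one class, on a time grid for plotting."""
    if grid is None:
        grid = np.linspace(t0, T, 25)
    grid = np.asarray(grid, dtype=float)
    bands = np.array([midrange_band(class_params, t, coverage) for t in grid])
    return {
        "grid": grid,
        "mean": class_params.mean(grid),
        "sd": np.array([trajectory_sd(class_params, t) for t in grid]),
        "band_lower": bands[:, 0],
        "band_upper": bands[:, 1],
        "slope_on_intercept": class_params.psi[0, 1] / class_params.psi[0, 0]
        if class_params.psi[0, 0] > 0 else float("nan"),
        "pct_change_deviation": pct_change_deviation(class_params, t0, T)
        if class_params.psi[0, 0] > 0 else float("nan"),
        "standardized_deviation_at_T":
        standardized_deviation_at_T(class_params, a0, t0, T)
        if class_params.psi[0, 0] > 0 and trajectory_sd(class_params, T) > 0
        else float("nan"),
        "prob_positive_slope": prob_positive_slope(class_params.corr, a0),
        "a0": a0, "t0": t0, "T": T,
    }


def posterior_heterogeneity(draws, class_index: int, t0: float, T: float,
                            a0: float = 2.0, mode: str = "draws") -> dict:
    """Posterior summaries of the scalar heterogeneity descriptors.

    ``mode="draws"`` averages the descriptor over posterior draws (the
    default: nonlinear functions of parameters should be averaged on the
    descriptor scale); ``mode="plug-in"`` evaluates the descriptor at the
    posterior mean parameters.  The two can differ noticeably, e.g. for
    the probability of a positive slope when the correlation is uncertain.
    """
    keys = ("pct_change_deviation", "standardized_deviation_at_T",
            "prob_positive_slope")
    if mode == "plug-in":
        pm = draws.posterior_mean_params()
        h = heterogeneity_summary(pm.classes[class_index], t0, T, a0=a0)
        return {k: h[k] for k in keys}
    if mode != "draws":
        raise ValueError("mode must be 'draws' or 'plug-in'")
    acc = {k: [] for k in keys}
    for c in range(draws.n_chains):
        for params in draws.iter_draws(c):
            cp = params.classes[class_index]
            if cp.psi[0, 0] <= 0:
                continue
            acc["pct_change_deviation"].append(pct_change_deviation(cp, t0, T))
            acc["standardized_deviation_at_T"].append(
                standardized_deviation_at_T(cp, a0, t0, T))
            acc["prob_positive_slope"].append(
                prob_positive_slope(cp.corr, a0))
    return {k: float(np.mean(v)) for k, v in acc.items()}


# ----------------------------------------------------------------------
# predictive criteria on the mixed (marginal) distribution

def pointwise_loglik(draws, data: LongitudinalDataset) -> np.ndarray:
    """(S, n) matrix of subject-level mixed log predictive densities.

    Entry (s, j) is log sum_k pi_k^(s) f_k^(s)(y_j); rows sum to the
    mixture log-likelihood of the corresponding draw.  Draws are stacked
    chain-major.
    """
    S = draws.n_chains * draws.n_iter
    out = np.empty((S, data.n_subjects))
    s = 0
    for c in range(draws.n_chains):
        for params in draws.iter_draws(c):
            logf, _ = _class_loglik_matrix(params, data)
            out[s] = logsumexp(logf + _log_mix_weights(params.pi), axis=1)
            s += 1
    return out


def waic(pointwise: np.ndarray) -> tuple[float, float, float]:
    """WAIC from an (S, n) pointwise log-likelihood matrix.

    Returns (elpd_waic, p_waic, waic) with
    lppd = sum_j log mean_s exp(ll_sj), p_waic = sum_j var_s(ll_sj),
    waic = -2 (lppd - p_waic).  The variance is the population form
    (1/S), so duplicating the draws leaves the result unchanged; a single
    draw gives p_waic = 0.
    """
    ll = np.atleast_2d(np.asarray(pointwise, dtype=float))
    S = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(S)))
    p = float(np.sum(ll.var(axis=0)))
    elpd = lppd - p
    return elpd, p, -2.0 * elpd


def loo(pointwise: np.ndarray):
    """PSIS-LOO expected log predictive density, delegated to arviz.

    Returns (elpd_loo, p_loo).
    """
    import warnings

    import arviz as az

    ll = np.atleast_2d(np.asarray(pointwise, dtype=float))
    ds = az.from_dict(
        posterior={"dummy": ll.sum(axis=1)[None, :]},
        log_likelihood={"y": ll[None, :, :]},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = az.loo(ds, pointwise=False)
    return float(res.elpd_loo), float(res.p_loo)
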