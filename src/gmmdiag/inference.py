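"""Posterior sampling and maximum marginal likelihood estimation.

Sampling targets the log posterior of the *marginalized* model (no
discrete class indicators, no per-subject random effects) via the HMC
backend in :mod:`gmmdiag.hmc`.  Initialization is Stan-style: every
unconstrained coordinate drawn Uniform(-2, 2), with the exponential /
tanh / softmax transforms mapping into the constrained space.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from .data import LongitudinalDataset
from .draws import DrawsStore, params_to_row
from .hmc import SamplerOptions, sample_chain
from .params import MixtureParams, ModelSpec, PriorConfig
from .transforms import (constrain, dim, initialize_unconstrained,
                         logpost_and_grad, unconstrain)


def initialize_params(spec: ModelSpec, seed: int) -> MixtureParams:
    """Random initial parameters, deterministic given the seed."""
    theta = initialize_unconstrained(spec.n_classes, seed)
    return constrain(theta, spec.n_classes)


def moments_init(data: LongitudinalDataset, K: int, seed: int,
                 jitter: float = 0.3) -> np.ndarray:
    """Data-informed starting point on the unconstrained scale.

    Subjects are split into K groups by quantiles of their mean response;
    per-group pooled OLS of y on (1, t, t^2) gives the trajectory
    coefficients.  Random-effect SDs start at a fraction of the residual
    spread, correlations at zero, class probabilities at the group
    proportions.  A Uniform(-jitter, jitter) perturbation keeps multiple
    chains from starting identically.

    Mixture posteriors have locally stable degenerate basins (empty or
    merged classes); diffuse random starts can land there and never
    leave.  Data-informed starts are standard practice for applied
    mixture fitting and are the recommended initialization for ``fit``
    runs, while diffuse Uniform(-2, 2) starts remain the default for
    studying prior-dependent pathology.
    """
    rng = np.random.default_rng(seed)
    df = data.to_frame()
    subj_means = df.groupby("id", sort=False)["y"].mean()
    qs = np.quantile(subj_means, np.linspace(0, 1, K + 1))
    qs[0] -= 1e-9
    group = np.searchsorted(qs, subj_means.to_numpy(), side="left") - 1
    group = np.clip(group, 0, K - 1)
    gid = dict(zip(subj_means.index, group))
    df["_g"] = df["id"].map(gid)

    theta = np.zeros(dim(K))
    betas = np.zeros((K, 3))
    resid_sd = []
    for k in range(K):
        sub = df[df["_g"] == k]
        if len(sub) < 4:
            betas[k] = (subj_means.mean(), 0.0, 0.0)
            resid_sd.append(df["y"].std() or 1.0)
            continue
        t = sub["time"].to_numpy()
        X = np.column_stack([np.ones_like(t), t, t**2])
        coef, res, *_ = np.linalg.lstsq(X, sub["y"].to_numpy(), rcond=None)
        betas[k] = coef
        fitted = X @ coef
        resid_sd.append(np.std(sub["y"].to_numpy() - fitted) or 1.0)
    sd0 = float(np.median(resid_sd))
    pi = np.bincount(group, minlength=K).astype(float)
    pi = np.clip(pi, 1.0, None)
    pi /= pi.sum()

    theta[:K - 1] = np.log(pi[:-1]) - np.log(pi[-1])
    theta[K - 1:K - 1 + 3 * K] = betas.ravel()
    i = K - 1 + 3 * K
    theta[i:i + K] = np.log(max(0.5 * sd0, 1e-3))       # sd_int
    theta[i + K:i + 2 * K] = np.log(max(0.2 * sd0, 1e-3))  # sd_slope
    # correlations start at 0 (atanh 0 = 0)
    theta[-1] = np.log(max(0.7 * sd0, 1e-3))
    return theta + rng.uniform(-jitter, jitter, size=dim(K))


def sample_posterior(data: LongitudinalDataset, spec: ModelSpec,
                     prior: PriorConfig, n_chains: int = 4,
                     warmup: int = 1000, iters: int = 1000,
                     seed: int = 1,
                     options: SamplerOptions | None = None,
                     init: str = "random") -> DrawsStore:
    """Run HMC chains on the marginalized posterior.

    Each chain gets an independent seed derived from ``seed``; random
    initial points with non-finite log posterior are redrawn up to the
    retry cap before erroring.  ``init`` is ``"random"`` for diffuse
    Uniform(-2, 2) starts, ``"moments"`` for data-informed starts (see
    :func:`moments_init`), or ``"ml"`` for jittered multi-start
    maximum-likelihood starts.
    """
    if data.n_subjects < 1:
        raise ValueError("data is empty")
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    opts = options or SamplerOptions()
    K = spec.n_classes

    def target(theta):
        return logpost_and_grad(theta, data, prior, K)

    theta_ml = None
    if init == "ml":
        # jittered maximum-marginal-likelihood starts (blavaan-style)
        best, _, _ = fit_ml(data, spec, n_starts=8, seed=int(seed) + 17)
        theta_ml = unconstrain(best)

    P = 7 * K + 1
    params = np.empty((n_chains, iters, P))
    lp = np.empty((n_chains, iters))
    energy = np.empty((n_chains, iters))
    divergent = np.empty((n_chains, iters), dtype=bool)
    nlf = np.empty((n_chains, iters), dtype=int)
    cap = np.empty((n_chains, iters), dtype=bool)
    chain_seeds = [int(seed) + 1000 * c for c in range(n_chains)]
    step_sizes = []

    for c, cseed in enumerate(chain_seeds):
        rng = np.random.default_rng(cseed)
        theta0 = None
        for attempt in range(opts.init_retries):
            if init == "random":
                cand = initialize_unconstrained(K, cseed + 7919 * (attempt + 1))
            elif init == "moments":
                cand = moments_init(data, K, cseed + 7919 * (attempt + 1))
            elif init == "ml":
                jit_rng = np.random.default_rng(cseed + 7919 * (attempt + 1))
                cand = theta_ml + jit_rng.uniform(-0.02, 0.02,
                                                  size=len(theta_ml))
            else:
                raise ValueError(f"unknown init strategy {init!r}")
            with np.errstate(all="ignore"):
                lp0, _ = logpost_and_grad(cand, data, prior, K)
            if np.isfinite(lp0):
                theta0 = cand
                break
        if theta0 is None:
            raise RuntimeError(
                f"chain {c + 1}: no finite initial log posterior after "
                f"{opts.init_retries} attempts")
        try:
            out = sample_chain(target, theta0, warmup, iters, rng, opts)
        except Exception as e:  # surface with chain id
            raise RuntimeError(f"chain {c + 1} failed: {e}") from e
        for i in range(iters):
            params[c, i] = params_to_row(constrain(out["draws"][i], K))
        lp[c] = out["lp"]
        energy[c] = out["energy"]
        divergent[c] = out["divergent"]
        nlf[c] = out["n_leapfrog"]
        cap[c] = out["at_max_leapfrog"]
        step_sizes.append(out["step_size"])

    meta = {
        "seed": int(seed),
        "chain_seeds": chain_seeds,
        "warmup": warmup,
        "iters": iters,
        "prior": prior.label,
        "lkj_shape": prior.lkj_shape,
        "beta_sds": list(prior.beta_sds),
        "resid_sd_scale": prior.resid_sd_scale,
        "target_accept": opts.target_accept,
        "init_step_size": opts.init_step_size,
        "max_leapfrog": opts.max_leapfrog,
        "step_sizes": step_sizes,
        "init": init,
        "time_variable": spec.time_variable,
    }
    return DrawsStore(n_classes=K, params=params, lp=lp, energy=energy,
                      divergent=divergent, n_leapfrog=nlf,
                      at_max_leapfrog=cap, metadata=meta)


def fit_ml(data: LongitudinalDataset, spec: ModelSpec, n_starts: int = 20,
           seed: int = 1, tol: float = 1e-4):
    """Multi-start maximum marginal likelihood.

    Quasi-Newton (L-BFGS-B) on the unconstrained parameterization with
    analytic gradients.  Returns the best point, its log-likelihood, and
    the list of distinct local optima found (distinct after canonical
    label ordering, with log-likelihood differences above ``tol``).
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    K = spec.n_classes

    def neg(theta):
        try:
            with np.errstate(all="ignore"):
                lp, g = logpost_and_grad(theta, data, _FLAT_PRIOR, K,
                                         include_prior=False)
        except (np.linalg.LinAlgError, ValueError, FloatingPointError,
                OverflowError):
            return 1e12, np.zeros_like(theta)
        if not np.isfinite(lp) or not np.all(np.isfinite(g)):
            return 1e12, np.zeros_like(theta)
        return -lp, -g

    # first start: deterministic quantile-group moments; the rest are
    # overdispersed around it to sweep for local optima
    base = moments_init(data, K, seed, jitter=0.0)
    optima: list[tuple[float, MixtureParams]] = []
    n_converged = 0
    for s in range(n_starts):
        if s == 0:
            theta0 = base
        else:
            jitter = initialize_unconstrained(K, seed + 104729 * s)
            theta0 = base + jitter
        try:
            res = minimize(neg, theta0, jac=True, method="L-BFGS-B",
                           options={"maxiter": 500})
        except (np.linalg.LinAlgError, ValueError):
            continue
        if not np.isfinite(res.fun) or res.fun >= 1e11:
            continue
        n_converged += 1
        ll = -float(res.fun)
        cand = constrain(res.x, K).canonical_order()
        for ll0, _ in optima:
            if abs(ll - ll0) <= tol:
                break
        else:
            optima.append((ll, cand))
    if n_converged == 0:
        raise RuntimeError("no optimization start converged")
    optima.sort(key=lambda t: -t[0])
    best_ll, best = optima[0]
    return best, best_ll, optima


# improper flat prior sentinel for include_prior=False paths
_FLAT_PRIOR = PriorConfig()
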