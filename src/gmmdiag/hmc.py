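"""Hamiltonian Monte Carlo sampler with warmup adaptation.

A self-contained gradient-based sampler for the marginalized growth
mixture posterior (or any differentiable log density on R^d):

* leapfrog integration with a diagonal metric,
* dual-averaging step-size adaptation toward a target acceptance rate,
* expanding-window estimation of the diagonal metric during warmup,
* trajectory lengths jittered uniformly up to ``int_time / step_size``
  (capped), which avoids resonant periodic behavior,
* divergence detection (energy error above a threshold) and an
  at-trajectory-cap flag, analogous to the divergent-transition and
  maximum-treedepth warnings of NUTS implementations.

The recorded per-iteration energy is the Hamiltonian right after momentum
refresh, the series the E-BFMI diagnostic is defined on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SamplerOptions:
    """Tuning knobs of the HMC backend."""

    target_accept: float = 0.8
    init_step_size: float = 1.0
    int_time: float = 1.0          # nominal trajectory length in time units
    max_leapfrog: int = 1024       # hard cap on leapfrog steps per draw
    divergence_threshold: float = 1000.0
    init_retries: int = 100

    @property
    def max_treedepth(self) -> int:
        """Cap expressed on the log2 scale used by tree-based samplers."""
        return int(np.ceil(np.log2(self.max_leapfrog)))


class _SafeTarget:
    """Wrap a log-density-and-gradient callable; failures become -inf."""

    def __init__(self, logpost_grad):
        self._f = logpost_grad
        self.n_evals = 0

    def __call__(self, theta):
        self.n_evals += 1
        try:
            with np.errstate(all="ignore"):
                lp, grad = self._f(theta)
        except (np.linalg.LinAlgError, ValueError, FloatingPointError,
                OverflowError):
            return -np.inf, np.zeros_like(theta)
        if not np.isfinite(lp) or not np.all(np.isfinite(grad)):
            return (-np.inf if not np.isfinite(lp) else lp,
                    np.where(np.isfinite(grad), grad, 0.0))
        return lp, grad


def _find_initial_step_size(target, theta, lp, grad, inv_mass, eps, rng):
    """Stan-style heuristic: double/halve eps until the one-step
    acceptance probability crosses 1/2."""
    d = len(theta)
    p = rng.standard_normal(d) / np.sqrt(inv_mass)

    def one_step_dH(eps):
        with np.errstate(over="ignore", invalid="ignore"):
            p1 = p + 0.5 * eps * grad
            th1 = theta + eps * inv_mass * p1
            lp1, g1 = target(th1)
            p1 = p1 + 0.5 * eps * g1
            h0 = -lp + 0.5 * np.sum(p**2 * inv_mass)
            h1 = -lp1 + 0.5 * np.sum(p1**2 * inv_mass)
            return h1 - h0

    dH = one_step_dH(eps)
    if not np.isfinite(dH):
        dH = np.inf
    direction = 1 if dH < np.log(2.0) else -1
    for _ in range(50):
        eps_new = eps * (2.0 ** direction)
        dH = one_step_dH(eps_new)
        if not np.isfinite(dH):
            dH = np.inf
        if direction == 1 and not (dH < np.log(2.0)):
            break
        if direction == -1 and not (dH > np.log(2.0)):
            break
        eps = eps_new
        if eps < 1e-10 or eps > 1e7:
            break
    return eps


@dataclass
class _DualAveraging:
    """Nesterov dual averaging of log step size (Hoffman & Gelman)."""

    mu: float
    gamma: float = 0.05
    t0: float = 10.0
    kappa: float = 0.75
    _count: int = 0
    _h_bar: float = 0.0
    _log_eps_bar: float = 0.0

    def update(self, accept_stat: float, target: float) -> float:
        self._count += 1
        eta = 1.0 / (self._count + self.t0)
        self._h_bar = (1 - eta) * self._h_bar + eta * (target - accept_stat)
        log_eps = self.mu - np.sqrt(self._count) / self.gamma * self._h_bar
        w = self._count ** (-self.kappa)
        self._log_eps_bar = w * log_eps + (1 - w) * self._log_eps_bar
        return float(np.exp(log_eps))

    @property
    def adapted(self) -> float:
        return float(np.exp(self._log_eps_bar))


def _warmup_windows(n_warmup: int):
    """(init_buffer, metric windows, term_buffer) a la Stan."""
    init = max(int(0.15 * n_warmup), 10)
    term = max(int(0.10 * n_warmup), 10)
    middle = n_warmup - init - term
    if middle < 20:
        return n_warmup, [], 0
    windows = []
    w, pos = 25, 0
    while pos + w < middle:
        if pos + 3 * w >= middle:
            w = middle - pos
        windows.append(w)
        pos += w
        w *= 2
    if pos < middle:
        windows.append(middle - pos)
    return init, windows, term


def sample_chain(logpost_grad, theta0: np.ndarray, n_warmup: int, n_iter: int,
                 rng: np.random.Generator,
                 options: SamplerOptions | None = None,
                 collect_warmup: bool = False) -> dict:
    """Run one HMC chain; return kept draws and sampler metadata.

    Parameters
    ----------
    logpost_grad : callable
        theta -> (log density, gradient).
    theta0 : initial unconstrained position (must have finite density).
    n_warmup, n_iter : warmup and kept iteration counts.
    rng : seeded generator; the chain is deterministic given it.
    """
    opts = options or SamplerOptions()
    target = _SafeTarget(logpost_grad)
    theta = np.asarray(theta0, dtype=float).copy()
    d = len(theta)
    lp, grad = target(theta)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log posterior")

    inv_mass = np.ones(d)
    eps = _find_initial_step_size(target, theta, lp, grad, inv_mass,
                                  opts.init_step_size, rng)
    da = _DualAveraging(mu=np.log(2.0 * eps))

    init_buf, windows, term_buf = _warmup_windows(n_warmup)
    window_ends = []
    pos = init_buf
    for w in windows:
        pos += w
        window_ends.append(pos)
    window_draws: list[np.ndarray] = []

    warmup_trace = [] if collect_warmup else None
    draws = np.empty((n_iter, d))
    lps = np.empty(n_iter)
    energy = np.empty(n_iter)
    divergent = np.zeros(n_iter, dtype=bool)
    n_leapfrog = np.zeros(n_iter, dtype=int)
    at_cap = np.zeros(n_iter, dtype=bool)
    step_sizes_used = []

    total = n_warmup + n_iter
    errstate = np.errstate(over="ignore", invalid="ignore")
    errstate.__enter__()
    for it in range(total):
        warm = it < n_warmup
        # momentum refresh
        p = rng.standard_normal(d) / np.sqrt(inv_mass)
        h0 = -lp + 0.5 * np.sum(p**2 * inv_mass)

        L_nom = int(min(opts.max_leapfrog, max(1, round(opts.int_time / eps))))
        L = int(rng.integers(max(1, L_nom // 2), L_nom + 1))
        hit_cap = L_nom >= opts.max_leapfrog

        th_new, p_new, lp_new, g_new = theta, p, lp, grad
        diverged = False
        p_new = p_new + 0.5 * eps * g_new
        for step in range(L):
            th_new = th_new + eps * inv_mass * p_new
            lp_new, g_new = target(th_new)
            if not np.isfinite(lp_new):
                diverged = True
                break
            if step < L - 1:
                p_new = p_new + eps * g_new
            else:
                p_new = p_new + 0.5 * eps * g_new
            h_now = -lp_new + 0.5 * np.sum(p_new**2 * inv_mass)
            if h_now - h0 > opts.divergence_threshold:
                diverged = True
                break

        if diverged:
            accept_stat = 0.0
            accepted = False
        else:
            h1 = -lp_new + 0.5 * np.sum(p_new**2 * inv_mass)
            accept_stat = float(min(1.0, np.exp(min(0.0, h0 - h1))))
            accepted = np.log(rng.uniform()) < (h0 - h1)
        if accepted:
            theta, lp, grad = th_new, lp_new, g_new

        if warm:
            if collect_warmup:
                warmup_trace.append((theta.copy(), eps, accept_stat, lp))
            eps = da.update(accept_stat, opts.target_accept)
            eps = float(np.clip(eps, 1e-10, 1e7))
            if window_ends and it >= init_buf:
                window_draws.append(theta.copy())
            # metric update at window boundaries
            if window_ends and (it + 1) == window_ends[0]:
                X = np.asarray(window_draws)
                n_w = X.shape[0]
                if n_w >= 10:
                    var = X.var(axis=0, ddof=1)
                    # Stan-style shrinkage toward unit metric
                    var = (n_w / (n_w + 5.0)) * var \
                        + 1e-3 * (5.0 / (n_w + 5.0))
                    inv_mass = np.clip(var, 1e-10, 1e10)
                window_draws = []
                window_ends.pop(0)
                eps = _find_initial_step_size(target, theta, lp, grad,
                                              inv_mass, eps, rng)
                da = _DualAveraging(mu=np.log(2.0 * eps))
            if it + 1 == n_warmup:
                eps = da.adapted if da._count > 0 else eps
                eps = float(np.clip(eps, 1e-10, 1e7))
        else:
            i = it - n_warmup
            draws[i] = theta
            lps[i] = lp
            energy[i] = h0
            divergent[i] = diverged
            n_leapfrog[i] = L
            at_cap[i] = hit_cap
            step_sizes_used.append(eps)

    errstate.__exit__(None, None, None)
    return {
        "draws": draws,
        "lp": lps,
        "energy": energy,
        "divergent": divergent,
        "n_leapfrog": n_leapfrog,
        "at_max_leapfrog": at_cap,
        "step_size": float(np.mean(step_sizes_used)) if step_sizes_used else eps,
        "n_grad_evals": target.n_evals,
        "warmup_trace": warmup_trace,
    }
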