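"""Convergence statistics: rank-normalized split R-hat, ESS, E-BFMI.

R-hat is the maximum of the rank-normalized split form and the
rank-normalized folded-split form (computed on absolute deviations from
the median), with bulk and tail effective sample sizes, following
Vehtari, Gelman, Simpson, Carpenter & Bürkner (2021).  The heavy lifting
is delegated to ``arviz``; the degenerate case in which every chain is
constant is intercepted first and reported as an infinite R-hat with
unavailable (NaN) ESS, the convention of the ``posterior`` R package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

RHAT_THRESHOLD = 1.10
EBFMI_THRESHOLD = 0.3


@dataclass
class ConvergenceStats:
    """Per-parameter R-hat / ESS plus per-chain sampler health."""

    parameters: list[str]
    rhat: np.ndarray          # (P,) max of rank-normalized split & folded
    ess_bulk: np.ndarray      # (P,)
    ess_tail: np.ndarray      # (P,)
    e_bfmi: np.ndarray        # (n_chains,) NaN when undefined
    n_divergent: np.ndarray   # (n_chains,)
    n_max_treedepth: np.ndarray  # (n_chains,)

    @property
    def flagged(self) -> list[str]:
        """Parameters with R-hat above 1.10 (or undefined/infinite)."""
        bad = ~(self.rhat <= RHAT_THRESHOLD)
        return [p for p, b in zip(self.parameters, bad) if b]

    @property
    def n_flagged(self) -> int:
        return len(self.flagged)

    @property
    def mean_rhat(self) -> float:
        """Mean R-hat over parameters where it is finite."""
        finite = self.rhat[np.isfinite(self.rhat)]
        return float(finite.mean()) if finite.size else float("inf")

    @property
    def low_ebfmi_chains(self) -> list[int]:
        with np.errstate(invalid="ignore"):
            return [int(c) for c in
                    np.nonzero(self.e_bfmi < EBFMI_THRESHOLD)[0]]


def ebfmi(energy) -> float:
    """Estimated Bayesian fraction of missing information for one chain.

    Var of successive energy differences over Var of the energy; values
    below 0.3 indicate inefficient momentum resampling.  Returns NaN for
    constant energy (undefined).
    """
    e = np.asarray(energy, dtype=float)
    if e.size < 2:
        raise ValueError("need at least 2 energy values")
    var_e = e.var()
    if var_e == 0:
        return float("nan")
    return float(np.mean(np.diff(e) ** 2) / var_e)


def _rhat_ess_matrix(x: np.ndarray):
    """(chains, draws) -> (rhat, ess_bulk, ess_tail) with degenerate
    handling before delegating to arviz."""
    import arviz as az

    if np.all(x.max(axis=1) == x.min(axis=1)):
        # every chain constant: within-chain variance is zero
        return float("inf"), float("nan"), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = float(az.rhat(az.convert_to_dataset(x))["x"].values)
        ess_b = float(az.ess(az.convert_to_dataset(x), method="bulk")["x"].values)
        ess_t = float(az.ess(az.convert_to_dataset(x), method="tail")["x"].values)
    if np.isnan(rhat):
        rhat = float("inf")
    return rhat, ess_b, ess_t


def convergence_stats(draws) -> ConvergenceStats:
    """Compute the convergence report for a :class:`DrawsStore`.

    Requires >= 2 chains and >= 4 kept draws per chain.  Degenerate cases
    (all-constant chains) are reported, not raised.
    """
    if draws.n_chains < 2:
        raise ValueError("need >= 2 chains for R-hat")
    if draws.n_iter < 4:
        raise ValueError("need >= 4 kept draws per chain")
    names = draws.columns
    P = len(names)
    rhat = np.empty(P)
    ess_b = np.empty(P)
    ess_t = np.empty(P)
    for j in range(P):
        rhat[j], ess_b[j], ess_t[j] = _rhat_ess_matrix(draws.params[:, :, j])

    n_chains = draws.n_chains
    e_bfmi = np.full(n_chains, np.nan)
    if draws.energy is not None:
        for c in range(n_chains):
            e_bfmi[c] = ebfmi(draws.energy[c])
    n_div = (draws.divergent.sum(axis=1) if draws.divergent is not None
             else np.zeros(n_chains, dtype=int))
    n_cap = (draws.at_max_leapfrog.sum(axis=1)
             if draws.at_max_leapfrog is not None
             else np.zeros(n_chains, dtype=int))
    return ConvergenceStats(parameters=names, rhat=rhat, ess_bulk=ess_b,
                            ess_tail=ess_t, e_bfmi=e_bfmi,
                            n_divergent=np.asarray(n_div),
                            n_max_treedepth=np.asarray(n_cap))
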