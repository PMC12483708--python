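"""Kullback–Leibler (Stephens) relabeling of mixture draws.

The mixture likelihood is invariant to permutations of the class labels,
so MCMC output can switch labels between and within chains.  Stephens'
algorithm 2 finds, for every kept draw s, a permutation nu_s of the
labels making the permuted posterior classification probability matrices
P^(s) as similar as possible across draws.  It alternates

  (i)  Q = mean over draws of the permuted P^(s);
  (ii) per draw, the permutation minimizing
       sum_j sum_k P_jk log(P_jk / Q_jk),

until no permutation changes.  The objective is non-increasing across
sweeps and the fixed point is deterministic given the input.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

_CLIP = 1e-12
_MAX_SWEEPS = 100
_ENUM_K = 6  # full enumeration of K! up to here, Hungarian above


@dataclass
class RelabelingResult:
    """Per-draw permutations and the KL objective trace.

    ``permutations[s]`` maps new labels to old: new class k of draw s is
    old class ``permutations[s][k]``.
    """

    permutations: np.ndarray    # (S, K) int
    objective_trace: list[float]
    n_sweeps: int
    converged: bool = True

    def __post_init__(self):
        K = self.permutations.shape[1]
        ref = np.arange(K)
        for s, p in enumerate(self.permutations):
            if not np.array_equal(np.sort(p), ref):
                raise ValueError(f"row {s} is not a permutation of 0..K-1")


def _kl_cost_matrix(P: np.ndarray, logQ: np.ndarray) -> np.ndarray:
    """cost[a, b] = contribution of assigning old class a to new slot b."""
    Pc = np.clip(P, _CLIP, 1.0)
    # sum_j P_ja (log P_ja - log Q_jb)
    plogp = np.sum(Pc * np.log(Pc), axis=0)            # (K,)
    cross = Pc.T @ logQ                                # (K, K): [a, b]
    return plogp[:, None] - cross


def _best_perm(P: np.ndarray, logQ: np.ndarray) -> tuple[np.ndarray, float]:
    """Permutation (new->old) minimizing the per-draw KL term."""
    K = P.shape[1]
    cost = _kl_cost_matrix(P, logQ)
    if K <= _ENUM_K:
        best, best_val = None, np.inf
        for perm in itertools.permutations(range(K)):
            val = sum(cost[perm[b], b] for b in range(K))
            if val < best_val - 1e-15:
                best_val, best = val, perm
        return np.asarray(best), float(best_val)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(K, dtype=int)
    perm[cols] = rows
    return perm, float(cost[rows, cols].sum())


def stephens_relabel(probs: np.ndarray, max_sweeps: int = _MAX_SWEEPS) -> RelabelingResult:
    """Run Stephens' KL relabeling on an (S, n, K) probability array."""
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 3:
        raise ValueError("probs must be (S, n, K)")
    S, n, K = probs.shape
    rowsums = probs.sum(axis=2)
    if np.any(probs < -1e-9) or np.any(np.abs(rowsums - 1.0) > 1e-6):
        raise ValueError("classification probabilities are not on the simplex")

    perms = np.tile(np.arange(K), (S, 1))
    trace: list[float] = []
    converged = False
    for sweep in range(max_sweeps):
        permuted = np.take_along_axis(probs, perms[:, None, :], axis=2)
        Q = permuted.mean(axis=0)
        logQ = np.log(np.clip(Q, _CLIP, 1.0))
        total = 0.0
        changed = False
        for s in range(S):
            perm, val = _best_perm(probs[s], logQ)
            total += val
            if not np.array_equal(perm, perms[s]):
                perms[s] = perm
                changed = True
        trace.append(total)
        if not changed:
            converged = True
            break
    else:
        import warnings
        warnings.warn(f"relabeling did not settle within {max_sweeps} sweeps")
    return RelabelingResult(permutations=perms, objective_trace=trace,
                            n_sweeps=len(trace), converged=converged)


def kl_objective(probs: np.ndarray, perms: np.ndarray) -> float:
    """Evaluate the Stephens objective for given permutations."""
    permuted = np.take_along_axis(np.asarray(probs, float),
                                  np.asarray(perms)[:, None, :], axis=2)
    Q = permuted.mean(axis=0)
    Pc = np.clip(permuted, _CLIP, 1.0)
    Qc = np.clip(Q, _CLIP, 1.0)
    return float(np.sum(Pc * (np.log(Pc) - np.log(Qc)[None])))


def apply_relabeling(draws, result: RelabelingResult):
    """Return a new DrawsStore with class-indexed parameters permuted.

    ``result`` must cover all kept draws, chain-major: permutation row
    ``c * n_iter + i`` applies to chain c, iteration i.  Non-class
    parameters (sigma, log posterior, sampler series) are untouched, so
    the mixture log-likelihood of every draw is unchanged.
    """
    from .draws import DrawsStore

    S = draws.n_chains * draws.n_iter
    if result.permutations.shape != (S, draws.n_classes):
        raise ValueError(
            f"permutation array {result.permutations.shape} does not match "
            f"{S} kept draws with K={draws.n_classes}")
    K = draws.n_classes
    perms = result.permutations.reshape(draws.n_chains, draws.n_iter, K)
    new_params = draws.params.copy()
    for b, base in enumerate(("pi", "beta0", "beta1", "beta2", "sd_int",
                              "sd_slope", "corr")):
        block = draws.params[:, :, b * K:(b + 1) * K]
        new_params[:, :, b * K:(b + 1) * K] = np.take_along_axis(block, perms,
                                                                 axis=2)
    return DrawsStore(n_classes=K, params=new_params, lp=draws.lp.copy(),
                      energy=None if draws.energy is None else draws.energy.copy(),
                      divergent=None if draws.divergent is None else draws.divergent.copy(),
                      n_leapfrog=None if draws.n_leapfrog is None else draws.n_leapfrog.copy(),
                      at_max_leapfrog=None if draws.at_max_leapfrog is None
                      else draws.at_max_leapfrog.copy(),
                      metadata={**draws.metadata, "relabeled": True})
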