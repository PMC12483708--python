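"""Diagnostics for degenerate MCMC behavior in mixture models.

Four-step screening procedure:

1. R-hat screening — count parameters with R-hat above 1.10 (infinite
   R-hat included), report the mean over finite values.
2. Stuck-sequence detection — trailing moving standard deviations of the
   smallest class-probability series; a maximal run of q consecutive
   zero-SD windows of size h means the chain was literally unchanged for
   q + h - 1 iterations.
3. Twinlike-class detection — a distinguishability index (DI) per class
   pair and iteration: 0 when the two class-specific densities are
   identical for every subject, 100 when every subject is assigned to
   one class with certainty.  Persistently small DI signals two classes
   collapsing onto each other.
4. Miniscule-class detection — route A clusters (moving average, moving
   SD) of the smallest class probability with 2-means and flags the
   cluster whose centroid sits near the origin; route B flags runs of
   consecutive iterations in which the DI against the smallest class
   exceeds a high threshold (that class's parameters wander the prior,
   so it is almost perfectly distinguishable from the data-supported
   classes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit, xlogy

from .data import LongitudinalDataset
from .likelihood import _class_loglik_matrix
from .params import MixtureParams

LOG2 = np.log(2.0)


# ----------------------------------------------------------------------
# moving statistics

def moving_sd(series, h: int = 10) -> np.ndarray:
    """Trailing moving sample SD with window size h.

    ``out[j]`` is the SD of ``series[j : j + h]`` (the window *ending* at
    iteration ``j + h - 1``); the output has ``len(series) - h + 1``
    entries, earlier positions being undefined.  Windows whose values are
    literally constant yield exactly 0.0.
    """
    x = np.asarray(series, dtype=float)
    if h < 2:
        raise ValueError("window size h must be >= 2")
    if x.ndim != 1 or len(x) < h:
        raise ValueError(f"series shorter than window h={h}")
    win = sliding_window_view(x, h)
    out = win.std(axis=1, ddof=1)
    constant = win.max(axis=1) == win.min(axis=1)
    out[constant] = 0.0
    return out


def moving_average(series, h: int = 10) -> np.ndarray:
    """Trailing moving mean, aligned exactly like :func:`moving_sd`."""
    x = np.asarray(series, dtype=float)
    if h < 2:
        raise ValueError("window size h must be >= 2")
    if x.ndim != 1 or len(x) < h:
        raise ValueError(f"series shorter than window h={h}")
    return sliding_window_view(x, h).mean(axis=1)


def _runs(mask: np.ndarray):
    """Maximal runs of True: list of (start_index, run_length)."""
    out = []
    i, n = 0, len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j - i))
            i = j
        else:
            i += 1
    return out


@dataclass
class StuckReport:
    """Stuck sequences of one chain.

    ``runs`` holds (start_iteration, run_length) pairs in iteration
    units: a run of q zero-SD windows starting at window j is reported as
    start j, length q + h - 1.  Runs are non-overlapping and sorted.
    """

    runs: list[tuple[int, int]]
    persistently_stuck: bool
    h: int
    min_run: int

    @property
    def n_sequences(self) -> int:
        return len(self.runs)


def detect_stuck(series, h: int = 10, min_run: int = 20) -> StuckReport:
    """Detect maximal stuck sequences of at least ``min_run`` iterations."""
    msd = moving_sd(series, h=h)
    zero = msd == 0.0
    runs = []
    for start, q in _runs(zero):
        length = q + h - 1
        if length >= min_run:
            runs.append((start, length))
    persistent = bool(zero.all()) and len(zero) > 0
    return StuckReport(runs=runs, persistently_stuck=persistent,
                       h=h, min_run=min_run)


# ----------------------------------------------------------------------
# distinguishability index

def _pair_di_from_logf(logf_k: np.ndarray, logf_l: np.ndarray,
                       subject_ids=None) -> float:
    both_dead = ~np.isfinite(logf_k) & ~np.isfinite(logf_l)
    if both_dead.any():
        j = int(np.nonzero(both_dead)[0][0])
        sid = subject_ids[j] if subject_ids is not None else j
        raise FloatingPointError(
            f"both class densities underflow for subject {sid!r}")
    p = expit(logf_k - logf_l)
    ent = -(xlogy(p, p) + xlogy(1.0 - p, 1.0 - p))
    di = 100.0 * (1.0 - float(ent.mean()) / LOG2)
    return float(np.clip(di, 0.0, 100.0))


def distinguishability_index(params_draw: MixtureParams,
                             data: LongitudinalDataset,
                             pair: tuple[int, int]) -> float:
    """DI between classes k and l (0-based) for one parameter draw.

    Under equal class weights ("prior ignorance"), each subject's
    conditional probability of class k given k-or-l is
    ``p_j = f_k(y_j) / (f_k(y_j) + f_l(y_j))``, evaluated in log space.
    The DI is ``100 * (1 - mean_entropy / log 2)``: 0 for
    indistinguishable classes, 100 for perfectly separated ones.
    """
    k, l = pair
    K = params_draw.n_classes
    if k == l:
        raise ValueError("pair must name two distinct classes")
    if not (0 <= k < K and 0 <= l < K):
        raise ValueError(f"pair {pair} out of range for K={K}")
    logf, _ = _class_loglik_matrix(params_draw, data)
    return _pair_di_from_logf(logf[:, k], logf[:, l],
                              subject_ids=data.subject_order)


@dataclass
class DISeries:
    """Iteration-indexed DI values per chain and unordered class pair."""

    pairs: list[tuple[int, int]]
    values: np.ndarray  # (n_chains, n_pairs, n_iter), all in [0, 100]

    def __post_init__(self):
        v = self.values
        if np.any(v < -1e-9) or np.any(v > 100 + 1e-9):
            raise ValueError("DI values outside [0, 100]")

    def pair_index(self, k: int, l: int) -> int:
        a, b = min(k, l), max(k, l)
        return self.pairs.index((a, b))

    def for_pair(self, chain: int, k: int, l: int) -> np.ndarray:
        return self.values[chain, self.pair_index(k, l)]


def di_series(draws, data: LongitudinalDataset) -> DISeries:
    """Compute the DI for every chain, iteration and class pair."""
    K = draws.n_classes
    pairs = [(k, l) for k in range(K) for l in range(k + 1, K)]
    values = np.empty((draws.n_chains, len(pairs), draws.n_iter))
    for c in range(draws.n_chains):
        for i, params in enumerate(draws.iter_draws(c)):
            logf, _ = _class_loglik_matrix(params, data)
            for p, (k, l) in enumerate(pairs):
                values[c, p, i] = _pair_di_from_logf(
                    logf[:, k], logf[:, l], subject_ids=data.subject_order)
    return DISeries(pairs=pairs, values=values)


@dataclass
class TwinlikeFindings:
    """Runs of low DI (twinlike classes) per chain and pair."""

    persistent: list[dict]   # chain, pair, start, length
    isolated: list[dict]     # chain, pair, iteration (single-draw dips)
    threshold: float
    min_run: int

    @property
    def any_persistent(self) -> bool:
        return len(self.persistent) > 0


def detect_twinlike(di: DISeries, threshold: float = 5.0,
                    min_run: int = 2) -> TwinlikeFindings:
    """Flag chains/pairs whose DI stays below ``threshold``.

    Runs of at least ``min_run`` consecutive low-DI iterations are
    persistent findings; single-iteration dips are listed separately
    (they occur occasionally in healthy chains and are non-events).
    """
    persistent, isolated = [], []
    for c in range(di.values.shape[0]):
        for p, pair in enumerate(di.pairs):
            low = di.values[c, p] < threshold
            for start, length in _runs(low):
                if length >= min_run:
                    persistent.append({"chain": c, "pair": pair,
                                       "start": start, "length": length})
                else:
                    for i in range(start, start + length):
                        isolated.append({"chain": c, "pair": pair,
                                         "iteration": i})
    return TwinlikeFindings(persistent=persistent, isolated=isolated,
                            threshold=threshold, min_run=min_run)


# ----------------------------------------------------------------------
# miniscule-class detection

@dataclass
class MinisculeReport:
    """Miniscule-class findings for one chain.

    Segments are (start_iteration, length) pairs; clustering-route
    segments are indexed by the window-end iteration of the moving
    statistics.  ``centroids`` holds the 2-means centroids on the
    (moving average, moving SD) plane, miniscule cluster first when one
    was identified.
    """

    segments_clustering: list[tuple[int, int]]
    segments_di: list[tuple[int, int]]
    centroids: np.ndarray | None
    routes: list[str]
    excluded_stuck: bool = False

    @property
    def any(self) -> bool:
        return bool(self.segments_clustering or self.segments_di)


def detect_miniscule(pi_min_series, di_values=None, h: int = 10,
                     di_threshold: float = 95.0, di_run: int = 3,
                     trim_pct: float = 10.0, centroid_tol: float = 0.05,
                     persistently_stuck: bool = False,
                     seed: int = 0) -> MinisculeReport:
    """Detect miniscule-class behavior in one chain.

    Route A (clustering): 2-means on (moving average, moving SD) of the
    smallest class probability; if the smaller centroid lies near the
    origin (both coordinates below ``centroid_tol``), its iterations are
    candidate miniscule behavior, after removing the top ``trim_pct``
    percent by moving average within that cluster (conservative trim).
    Route B (DI rule): runs of at least ``di_run`` consecutive iterations
    with DI above ``di_threshold`` for the pair(s) involving the smallest
    class; skipped for persistently stuck chains, whose constant draws
    are a separate pathology.
    """
    from sklearn.cluster import KMeans

    pi_min = np.asarray(pi_min_series, dtype=float)
    ma = moving_average(pi_min, h=h)
    ms = moving_sd(pi_min, h=h)
    X = np.column_stack([ma, ms])

    segments_a: list[tuple[int, int]] = []
    centroids = None
    routes = []
    if len(np.unique(X, axis=0)) >= 2:
        km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(X)
        cents = km.cluster_centers_
        small = int(np.argmin(cents[:, 0]))
        if np.all(np.abs(cents[small]) < centroid_tol):
            centroids = np.vstack([cents[small], cents[1 - small]])
            d_small = np.linalg.norm(X - cents[small], axis=1)
            d_other = np.linalg.norm(X - cents[1 - small], axis=1)
            member = d_small < d_other  # ties -> non-miniscule
            if member.any():
                cut = np.percentile(ma[member], 100.0 - trim_pct)
                member &= ma <= cut
            # window index w ends at iteration w + h - 1
            segments_a = [(start + h - 1, length)
                          for start, length in _runs(member)]
            if segments_a:
                routes.append("clustering")

    segments_b: list[tuple[int, int]] = []
    if di_values is not None and not persistently_stuck:
        di = np.atleast_2d(np.asarray(di_values, dtype=float))
        high = np.all(di > di_threshold, axis=0)
        for start, length in _runs(high):
            if length >= di_run:
                segments_b.append((start, length))
        if segments_b:
            routes.append("DI-rule")

    return MinisculeReport(segments_clustering=segments_a,
                           segments_di=segments_b,
                           centroids=centroids, routes=routes,
                           excluded_stuck=persistently_stuck)


# ----------------------------------------------------------------------
# orchestration

@dataclass
class DiagnosticsConfig:
    window: int = 10
    min_run: int = 20
    twin_threshold: float = 5.0
    twin_min_run: int = 2
    di_threshold: float = 95.0
    di_run: int = 3
    trim_pct: float = 10.0
    centroid_tol: float = 0.05
    seed: int = 0


@dataclass
class DiagnosticsReport:
    """Structured output of the four-step screening."""

    n_rhat_flagged: int
    mean_rhat: float
    rhat_undefined: bool
    stuck: list[StuckReport]           # per chain
    twinlike: TwinlikeFindings
    miniscule: list[MinisculeReport]   # per chain
    di: DISeries
    n_divergent: list[int]
    n_max_treedepth: list[int]
    low_ebfmi_chains: list[int]
    config: DiagnosticsConfig

    @property
    def chains_with_stuck_sequences(self) -> list[int]:
        return [c for c, r in enumerate(self.stuck) if r.n_sequences > 0]

    @property
    def persistently_stuck_chains(self) -> list[int]:
        return [c for c, r in enumerate(self.stuck) if r.persistently_stuck]

    @property
    def chains_with_miniscule(self) -> list[int]:
        return [c for c, r in enumerate(self.miniscule) if r.any]

    def to_dict(self) -> dict:
        return {
            "step1": {"n_rhat_flagged": self.n_rhat_flagged,
                      "mean_rhat": self.mean_rhat,
                      "rhat_undefined": self.rhat_undefined},
            "step2": {"chains_with_stuck_sequences":
                      self.chains_with_stuck_sequences,
                      "persistently_stuck_chains":
                      self.persistently_stuck_chains,
                      "runs": [r.runs for r in self.stuck]},
            "step3": {"persistent": self.twinlike.persistent,
                      "isolated": self.twinlike.isolated},
            "step4": {"chains_with_miniscule": self.chains_with_miniscule,
                      "segments_clustering":
                      [r.segments_clustering for r in self.miniscule],
                      "segments_di": [r.segments_di for r in self.miniscule]},
            "sampler": {"n_divergent": self.n_divergent,
                        "n_max_treedepth": self.n_max_treedepth,
                        "low_ebfmi_chains": self.low_ebfmi_chains},
        }


def smallest_class(draws, chain: int) -> int:
    """Class with the smallest mean probability within one chain."""
    return int(np.argmin(draws.pi_draws()[chain].mean(axis=0)))


def diagnostics_report(draws, data: LongitudinalDataset,
                       config: DiagnosticsConfig | None = None,
                       di: DISeries | None = None) -> DiagnosticsReport:
    """Run the full four-step screening on sampled draws."""
    from .convergence import convergence_stats

    cfg = config or DiagnosticsConfig()
    if draws.n_chains >= 2 and draws.n_iter >= 4:
        cs = convergence_stats(draws)
        n_flagged = cs.n_flagged
        mean_rhat = cs.mean_rhat
        undefined = bool(np.any(~np.isfinite(cs.rhat)))
        n_div = [int(x) for x in cs.n_divergent]
        n_cap = [int(x) for x in cs.n_max_treedepth]
        low_ebfmi = cs.low_ebfmi_chains
    else:
        n_flagged, mean_rhat, undefined = 0, float("nan"), False
        n_div = ([int(x) for x in draws.divergent.sum(axis=1)]
                 if draws.divergent is not None else [0] * draws.n_chains)
        n_cap = ([int(x) for x in draws.at_max_leapfrog.sum(axis=1)]
                 if draws.at_max_leapfrog is not None else [0] * draws.n_chains)
        low_ebfmi = []

    pi = draws.pi_draws()                       # (chains, iters, K)
    pi_min = pi.min(axis=2)                     # smallest prob per iteration
    stuck = [detect_stuck(pi_min[c], h=cfg.window, min_run=cfg.min_run)
             for c in range(draws.n_chains)]

    if di is None:
        di = di_series(draws, data)
    twin = detect_twinlike(di, threshold=cfg.twin_threshold,
                           min_run=cfg.twin_min_run)

    miniscule = []
    for c in range(draws.n_chains):
        sk = smallest_class(draws, c)
        rows = [di.values[c, p] for p, pair in enumerate(di.pairs)
                if sk in pair]
        miniscule.append(detect_miniscule(
            pi_min[c], di_values=np.vstack(rows), h=cfg.window,
            di_threshold=cfg.di_threshold, di_run=cfg.di_run,
            trim_pct=cfg.trim_pct, centroid_tol=cfg.centroid_tol,
            persistently_stuck=stuck[c].persistently_stuck, seed=cfg.seed))

    return DiagnosticsReport(
        n_rhat_flagged=n_flagged, mean_rhat=mean_rhat,
        rhat_undefined=undefined, stuck=stuck, twinlike=twin,
        miniscule=miniscule, di=di, n_divergent=n_div,
        n_max_treedepth=n_cap, low_ebfmi_chains=low_ebfmi, config=cfg)
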