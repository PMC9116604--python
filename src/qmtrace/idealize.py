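"""Idealization of telegraph-noise current traces.

Pipeline: an all-point current histogram is fitted with a Gaussian
mixture (EM) to locate the conductance levels, then a segmental k-means
(SKM) loop alternates Viterbi decoding of the most likely state path —
under per-state Gaussian emissions and an estimated sample-to-sample
transition matrix — with re-estimation of the emission parameters from
the assigned samples and of the transition probabilities from path
counts.  Each half-step maximizes the joint log-likelihood of (path,
data) over one block of variables, so the SKM objective is
non-decreasing and the loop converges to a fixed point.

Dwell events are obtained by run-length encoding the converged path;
events shorter than the detection dead time are merged into their longer
neighbor (shortest first) because the acquisition filter makes them
unreliable.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from sklearn.mixture import GaussianMixture

from .models import DwellEvent, IVSweep, TimeTrace
from .simmons import SimmonsParams, simmons_current

__all__ = [
    "HistogramFit",
    "IdealizedTrace",
    "TransientScan",
    "StateCollapseError",
    "allpoint_histogram_fit",
    "skm_idealize",
    "extract_dwells",
    "default_dead_time",
    "detect_sweep_transients",
]

_SD_FLOOR = 1e-15  # amperes; keeps log-emissions finite on noiseless data


class StateCollapseError(RuntimeError):
    """Raised when a state captures too few samples to estimate emissions."""


@dataclass(frozen=True)
class HistogramFit:
    """Gaussian-mixture fit of the all-point current histogram.

    Components are sorted by ascending mean.  ``sd_floored`` flags
    components whose sd hit the numerical floor (separable, essentially
    noiseless levels).
    """

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    bic: float | None = None
    sd_floored: bool = False

    def __post_init__(self) -> None:
        means = np.asarray(self.means, float)
        sds = np.asarray(self.sds, float)
        weights = np.asarray(self.weights, float)
        if not (means.size == sds.size == weights.size >= 1):
            raise ValueError("component arrays must share length >= 1")
        if means.size > 1 and np.any(np.diff(means) <= 0):
            raise ValueError("component means must be strictly increasing")
        if np.any(sds <= 0):
            raise ValueError("component sds must be > 0")
        if not np.isclose(weights.sum(), 1.0, atol=1e-6):
            raise ValueError("weights must sum to 1")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)
        object.__setattr__(self, "weights", weights)

    @property
    def k(self) -> int:
        return int(self.means.size)


@dataclass(frozen=True)
class IdealizedTrace:
    """Converged SKM idealization: per-sample states plus emission model."""

    state_seq: np.ndarray
    level_means: np.ndarray
    level_sds: np.ndarray
    transition_probs: np.ndarray
    objective_trajectory: np.ndarray
    sample_interval: float
    converged: bool = True

    def __post_init__(self) -> None:
        means = np.asarray(self.level_means, float)
        if means.size > 1 and np.any(np.diff(means) <= 0):
            raise ValueError("level_means must be strictly increasing")
        seq = np.asarray(self.state_seq)
        if seq.min() < 0 or seq.max() >= means.size:
            raise ValueError("state indices out of range")

    @property
    def n_states(self) -> int:
        return int(self.level_means.size)


def _count_histogram_peaks(
    counts: np.ndarray, smooth_bins: float = 2.0, min_prominence: float = 0.02
) -> int:
    """Number of modes of the all-point histogram.

    Counts are Gaussian-smoothed over a couple of bins and peaks kept if
    their prominence exceeds ``min_prominence`` of the tallest peak —
    states rare enough to fall below that are not resolvable as levels
    anyway.
    """
    from scipy.ndimage import gaussian_filter1d
    from scipy.signal import find_peaks

    smoothed = gaussian_filter1d(counts.astype(float), smooth_bins)
    peaks, _ = find_peaks(smoothed, prominence=min_prominence * smoothed.max())
    return max(1, int(peaks.size))


def allpoint_histogram_fit(
    trace: TimeTrace,
    k: "int | str" = "auto",
    max_samples: int = 200_000,
    n_bins: int = 200,
    random_state: int = 0,
) -> HistogramFit:
    """Fit a Gaussian mixture to every current sample of the trace.

    ``k='auto'`` counts the modes of the (smoothed) all-point histogram
    and fits that many components, mirroring how an analyst picks the
    state count from histogram peaks.  Likelihood criteria (BIC/ICL)
    deliberately are not used for the count: on filtered telegraph data
    the filter's transition ramps deposit a few percent of samples
    between the levels, which those criteria correctly—but
    unhelpfully—model as an extra between-level component.  Traces
    longer than ``max_samples`` are decimated with a deterministic
    stride before EM — the all-point histogram of a stationary trace is
    unchanged by decimation, and EM on 2e5 points already pins the
    component means far below the level spacing.
    """
    x = trace.current
    stride = max(1, int(np.ceil(x.size / max_samples)))
    xs = x[::stride]
    mu, s = float(xs.mean()), float(xs.std())
    bin_edges = np.histogram_bin_edges(x, bins=n_bins)
    counts, _ = np.histogram(x, bins=bin_edges)

    if isinstance(k, str):
        if k != "auto":
            raise ValueError("k must be an integer or 'auto'")
        k = _count_histogram_peaks(counts) if s > 0 else 1
        k = max(1, min(6, k, x.size // 10))
        if x.size < 10:
            raise ValueError("trace too short for a mixture fit")
    if not (1 <= k <= 6):
        raise ValueError("k must lie in [1, 6]")
    if x.size < 10 * k:
        raise ValueError(f"need at least {10 * k} samples for k={k}")

    if s == 0.0:  # constant trace: degenerate single component
        return HistogramFit(
            means=np.array([mu]),
            sds=np.array([_SD_FLOOR]),
            weights=np.array([1.0]),
            bin_edges=bin_edges,
            counts=counts,
            bic=None,
            sd_floored=True,
        )

    z = ((xs - mu) / s).reshape(-1, 1)
    best = GaussianMixture(
        n_components=k,
        covariance_type="full",
        reg_covar=1e-10,
        n_init=2,
        random_state=random_state,
        max_iter=300,
    ).fit(z)

    means = best.means_.ravel() * s + mu
    sds = np.sqrt(best.covariances_.ravel()) * s
    weights = best.weights_.ravel()
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    if means.size > 1 and np.any(np.diff(means) <= 0):
        raise StateCollapseError(
            f"mixture components collapsed onto {np.unique(means).size} "
            f"distinct levels; lower k"
        )
    floored = bool(np.any(sds <= 10 * _SD_FLOOR) or np.any(sds < 1e-4 * s))
    sds = np.maximum(sds, _SD_FLOOR)
    return HistogramFit(
        means=means,
        sds=sds,
        weights=weights / weights.sum(),
        bin_edges=bin_edges,
        counts=counts,
        bic=float(best.bic(z)),
        sd_floored=floored,
    )


@njit(cache=False)
def _viterbi(x, means, sds, log_A, log_pi):  # pragma: no cover - numba kernel
    T = x.shape[0]
    K = means.shape[0]
    inv2 = np.empty(K)
    lognorm = np.empty(K)
    for k in range(K):
        inv2[k] = -0.5 / (sds[k] * sds[k])
        lognorm[k] = -np.log(sds[k]) - 0.9189385332046727  # 0.5*log(2*pi)
    delta = np.empty(K)
    new_delta = np.empty(K)
    psi = np.empty((T, K), dtype=np.int8)
    for k in range(K):
        dd = x[0] - means[k]
        delta[k] = log_pi[k] + lognorm[k] + inv2[k] * dd * dd
    for t in range(1, T):
        for k in range(K):
            best = delta[0] + log_A[0, k]
            arg = 0
            for j in range(1, K):
                v = delta[j] + log_A[j, k]
                if v > best:  # strict: lowest predecessor index wins ties
                    best = v
                    arg = j
            dd = x[t] - means[k]
            new_delta[k] = best + lognorm[k] + inv2[k] * dd * dd
            psi[t, k] = arg
        for k in range(K):
            delta[k] = new_delta[k]
    best = delta[0]
    arg = 0
    for k in range(1, K):
        if delta[k] > best:
            best = delta[k]
            arg = k
    path = np.empty(T, dtype=np.int8)
    path[T - 1] = arg
    for t in range(T - 1, 0, -1):
        path[t - 1] = psi[t, path[t]]
    return path, best


def viterbi_decode(
    x: np.ndarray,
    means: np.ndarray,
    sds: np.ndarray,
    trans: np.ndarray,
    pi: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Most likely state path under Gaussian emissions (exposed for tests).

    Ties in log-probability resolve to the lowest state index.
    """
    log_A = np.log(np.maximum(np.asarray(trans, float), 1e-300))
    log_pi = np.log(np.maximum(np.asarray(pi, float), 1e-300))
    path, loglik = _viterbi(
        np.ascontiguousarray(x, dtype=np.float64),
        np.asarray(means, np.float64),
        np.asarray(sds, np.float64),
        np.ascontiguousarray(log_A),
        np.ascontiguousarray(log_pi),
    )
    return path.astype(np.int64), float(loglik)


def _initial_transitions(k: int, sample_interval: float, expected_dwell: float = 1e-3) -> np.ndarray:
    """Neutral starting transition matrix: self-transition probability from
    an expected dwell of 1 ms, remainder spread uniformly."""
    if k == 1:
        return np.ones((1, 1))
    p_stay = float(np.exp(-sample_interval / expected_dwell))
    a = np.full((k, k), (1.0 - p_stay) / (k - 1))
    np.fill_diagonal(a, p_stay)
    return a


def skm_idealize(
    trace: TimeTrace,
    k: "int | str" = "auto",
    init: HistogramFit | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    shared_sd: bool = False,
    min_state_samples: int = 10,
) -> IdealizedTrace:
    """Segmental k-means idealization of a current trace.

    Deterministic given the trace and initialization.  States in the
    returned object are sorted by ascending level mean regardless of the
    initialization order.  ``shared_sd`` pools a single noise sd across
    states (per-state sds are the default).

    Raises
    ------
    StateCollapseError
        If a state captures fewer than ``min_state_samples`` samples —
        the requested k exceeds the distinct-level support; lower k.
    """
    if init is None:
        init = allpoint_histogram_fit(trace, k=k)
    elif isinstance(k, int) and init.k != k:
        raise ValueError("init has a different component count than k")
    kk = init.k
    x = trace.current

    means = init.means.copy()
    sds = np.maximum(init.sds.copy(), _SD_FLOOR)
    pi = init.weights.copy()
    trans = _initial_transitions(kk, trace.sample_interval)

    objective: list[float] = []
    path = None
    for _ in range(max_iter):
        path, loglik = viterbi_decode(x, means, sds, trans, pi)
        objective.append(loglik)

        counts = np.bincount(path, minlength=kk)
        if np.any(counts < min_state_samples):
            bad = int(np.argmin(counts))
            raise StateCollapseError(
                f"state {bad} captured only {counts[bad]} samples; "
                f"the trace does not support k={kk} — lower k"
            )
        sums = np.bincount(path, weights=x, minlength=kk)
        means = sums / counts
        sq = np.bincount(path, weights=(x - means[path]) ** 2, minlength=kk)
        if shared_sd:
            sds = np.full(kk, max(np.sqrt(sq.sum() / x.size), _SD_FLOOR))
        else:
            sds = np.maximum(np.sqrt(sq / counts), _SD_FLOOR)

        if kk > 1:
            pair_counts = np.zeros((kk, kk))
            # bigram counts over the decoded path, self-transitions included
            idx = path[:-1] * kk + path[1:]
            flat = np.bincount(idx, minlength=kk * kk).reshape(kk, kk)
            pair_counts += flat
            row = pair_counts.sum(axis=1, keepdims=True)
            nonzero = row.ravel() > 0
            new_trans = trans.copy()
            new_trans[nonzero] = pair_counts[nonzero] / row[nonzero]
            trans = new_trans
        pi = np.zeros(kk)
        pi[path[0]] = 1.0

        if len(objective) >= 2:
            prev, cur = objective[-2], objective[-1]
            if abs(cur - prev) <= tol * max(abs(prev), 1.0):
                break
    converged = (
        len(objective) >= 2
        and abs(objective[-1] - objective[-2])
        <= tol * max(abs(objective[-2]), 1.0)
    ) or kk == 1

    order = np.argsort(means)
    remap = np.empty(kk, dtype=np.int64)
    remap[order] = np.arange(kk)
    return IdealizedTrace(
        state_seq=remap[path],
        level_means=means[order],
        level_sds=sds[order],
        transition_probs=trans[np.ix_(order, order)],
        objective_trajectory=np.array(objective),
        sample_interval=trace.sample_interval,
        converged=bool(converged),
    )


def default_dead_time(filter_cutoff: float | None, n_rise: float = 1.0) -> float:
    """Detection dead time from the acquisition filter's 10-90% rise time.

    A low-pass filter with cutoff f_c has rise time ~0.34/f_c; events
    shorter than one rise time never develop full amplitude and are
    detected unreliably, so they are merged away and the lifetime MLE
    truncates its likelihood at this dead time.  One rise time is the
    shortest window that still swallows the spurious 1-3 sample
    pass-through states a filtered multi-level step creates; longer
    windows discard reliably detected events, whose merging fuses
    same-state neighbors and biases lifetimes upward.  Returns
    ``n_rise * 0.34 / filter_cutoff`` (0 for unfiltered data).
    """
    if filter_cutoff is None:
        return 0.0
    return n_rise * 0.34 / filter_cutoff


def extract_dwells(
    ideal: IdealizedTrace,
    sample_interval: float | None = None,
    dead_time: float = 0.0,
) -> list[DwellEvent]:
    """Run-length encode a state sequence into dwell events.

    Events shorter than ``dead_time`` are merged into their longer
    neighbor, shortest first and recursively; merges that leave two
    same-state events adjacent fuse them into one.  All bookkeeping is
    done in integer sample counts, so total dwell time is conserved
    exactly through merging.  The first and last events are flagged
    censored (their true duration extends beyond the trace).
    """
    if dead_time < 0:
        raise ValueError("dead_time must be >= 0")
    dt = ideal.sample_interval if sample_interval is None else sample_interval
    seq = np.asarray(ideal.state_seq)
    boundaries = np.flatnonzero(np.diff(seq)) + 1
    starts_idx = np.concatenate([[0], boundaries])
    lens = np.diff(np.concatenate([starts_idx, [seq.size]])).astype(np.int64)
    states = seq[starts_idx].astype(np.int64)

    n = states.size
    if dead_time > 0 and n > 1:
        dead_samples = dead_time / dt
        prev = np.arange(-1, n - 1)
        nxt = np.arange(1, n + 1)
        nxt[-1] = -1
        alive = np.ones(n, dtype=bool)
        heap = [(int(lens[i]), i) for i in range(n) if lens[i] < dead_samples]
        heapq.heapify(heap)
        while heap:
            length, i = heapq.heappop(heap)
            if not alive[i]:
                continue
            if lens[i] != length:  # grew since pushed; re-queue if still short
                if lens[i] < dead_samples:
                    heapq.heappush(heap, (int(lens[i]), i))
                continue
            p, nx = prev[i], nxt[i]
            if p == -1 and nx == -1:
                break  # everything merged into one event
            if p == -1:
                target = nx
            elif nx == -1:
                target = p
            else:
                target = p if lens[p] >= lens[nx] else nx
            other = nx if target == p else p
            lens[target] += lens[i]
            alive[i] = False
            if target == p:
                nxt[p] = nx
                if nx != -1:
                    prev[nx] = p
            else:
                prev[nx] = p
                if p != -1:
                    nxt[p] = nx
            # fuse if the absorber now borders a same-state event
            if other != -1 and alive[other] and states[other] == states[target]:
                lens[target] += lens[other]
                alive[other] = False
                if target == p:  # other is on the right
                    nxt[target] = nxt[other]
                    if nxt[other] != -1:
                        prev[nxt[other]] = target
                else:
                    prev[target] = prev[other]
                    if prev[other] != -1:
                        nxt[prev[other]] = target
        states = states[alive]
        lens = lens[alive]

    starts = np.concatenate([[0], np.cumsum(lens)[:-1]])
    n = states.size
    return [
        DwellEvent(
            state=int(states[i]),
            start=float(starts[i] * dt),
            t_D=float(lens[i] * dt),
            censored=(i == 0 or i == n - 1),
        )
        for i in range(n)
    ]


@dataclass(frozen=True)
class TransientScan:
    """Transient events found on an I-V sweep above a Simmons baseline."""

    events: list[dict] = field(default_factory=list)
    threshold: float = 0.0
    baseline_warn: bool = False

    @property
    def n_events(self) -> int:
        return len(self.events)


def detect_sweep_transients(
    sweep: IVSweep,
    baseline: SimmonsParams,
    threshold_sigma: float = 3.0,
) -> TransientScan:
    """Flag bias-dependent excess-current transients on an I-V sweep.

    The residual r(V) = I_obs - I_Simmons(V) is thresholded at
    ``threshold_sigma`` times its robust sd (1.4826 x MAD, re-estimated
    from sub-threshold points in a second pass so wide transients do
    not inflate the noise scale); contiguous super-threshold runs —
    single-point dropouts bridged — become events with onset bias and
    peak excess.  If the baseline misfits badly (residual sd above half
    the signal range) the scan proceeds but sets ``baseline_warn``.
    """
    r = sweep.current - simmons_current(baseline, sweep.bias)

    def _robust_sd(values: np.ndarray) -> float:
        return 1.4826 * float(np.median(np.abs(values - np.median(values))))

    robust_sd = _robust_sd(r)
    for _ in range(3):  # iterate: transients out of the scale estimate
        if robust_sd <= 0:
            break
        quiet = np.abs(r - np.median(r)) <= 3.0 * robust_sd
        if quiet.sum() < 5:
            break
        refined = _robust_sd(r[quiet])
        if refined <= 0 or abs(refined - robust_sd) <= 1e-3 * robust_sd:
            break
        robust_sd = refined
    warn = robust_sd > 0.5 * float(np.ptp(sweep.current))
    scale = max(float(np.max(np.abs(sweep.current))), 1e-30)
    threshold = max(threshold_sigma * robust_sd, 1e-9 * scale)
    mask = r > threshold
    # bridge single-point dropouts inside a transient
    interior = mask[:-2] & ~mask[1:-1] & mask[2:]
    mask[1:-1] |= interior

    events = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            seg = r[i : j + 1]
            events.append(
                {
                    "onset_bias": float(sweep.bias[i]),
                    "end_bias": float(sweep.bias[j]),
                    "peak_excess": float(seg.max()),
                    "n_points": int(j - i + 1),
                }
            )
            i = j + 1
        else:
            i += 1
    return TransientScan(events=events, threshold=threshold, baseline_warn=warn)
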