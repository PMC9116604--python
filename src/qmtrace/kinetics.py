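"""Kinetic read-outs from idealized traces.

Per-state lifetimes come from the exponential maximum-likelihood
estimator with left truncation at the detection dead time: for observed
dwells t > t_dead of an exponential state, tau_hat = mean(t) - t_dead,
with asymptotic standard error tau_hat / sqrt(n).  Rates are k = 1/tau.
Occupancy is the time-weighted fraction of samples assigned to each
state; transition probabilities come from ordered event pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .idealize import IdealizedTrace
from .models import DwellEvent, IVSweep

__all__ = [
    "DwellFit",
    "KineticsSummary",
    "BiasSeries",
    "fit_dwell_mle",
    "kinetics_summary",
    "conductance_vs_bias",
    "conductance_ratio",
    "protein_conductance",
    "probe_yield",
]


@dataclass(frozen=True)
class DwellFit:
    tau: float
    se: float
    n: int


def fit_dwell_mle(
    durations: np.ndarray,
    censored: np.ndarray | None = None,
    dead_time: float = 0.0,
    censored_mode: str = "drop",
) -> DwellFit:
    """Exponential lifetime MLE with left truncation at ``dead_time``.

    ``censored_mode='drop'`` (default) excludes edge-censored dwells;
    ``'likelihood'`` keeps them as right-censored observations, for
    which the truncated-exponential MLE is
    tau_hat = sum_i (t_i - t_dead) / n_uncensored.
    SE is the asymptotic tau_hat / sqrt(n_uncensored).
    """
    t = np.asarray(durations, dtype=float)
    c = np.zeros(t.size, bool) if censored is None else np.asarray(censored, bool)
    if censored_mode not in ("drop", "likelihood"):
        raise ValueError("censored_mode must be 'drop' or 'likelihood'")
    keep = t > dead_time
    t, c = t[keep], c[keep]
    if censored_mode == "drop":
        t, c = t[~c], c[~c]
    n_unc = int(np.sum(~c))
    if n_unc < 2:
        raise ValueError("need at least 2 non-censored dwells above dead_time")
    tau = float(np.sum(t - dead_time) / n_unc)
    return DwellFit(tau=tau, se=tau / np.sqrt(n_unc), n=n_unc)


@dataclass(frozen=True)
class KineticsSummary:
    """Per-state lifetimes, rates, occupancies and transition structure.

    ``tau``/``rate`` entries are NaN for states without enough
    resolvable dwells (absent, not zero).  ``transition_probs`` rows sum
    to 1 wherever the state has outgoing events; the diagonal is zero by
    construction (run-length encoding forbids self-transitions).
    """

    tau: np.ndarray
    tau_se: np.ndarray
    rate: np.ndarray
    occupancy: np.ndarray
    transition_counts: np.ndarray
    transition_probs: np.ndarray
    n_events: np.ndarray
    level_means: np.ndarray
    bias: float
    dead_time: float = 0.0

    @property
    def n_states(self) -> int:
        return int(self.occupancy.size)

    @property
    def conductance(self) -> np.ndarray:
        """Per-state chord conductance G_i = level_mean_i / bias (S)."""
        if self.bias == 0:
            raise ValueError("conductance undefined at zero bias")
        return self.level_means / self.bias

    def to_dict(self) -> dict:
        def clean(a: np.ndarray) -> list:
            return [None if not np.isfinite(v) else float(v) for v in a]

        return {
            "bias_mV": self.bias * 1e3,
            "dead_time_ms": self.dead_time * 1e3,
            "per_state": [
                {
                    "tau_ms": None if not np.isfinite(self.tau[i]) else self.tau[i] * 1e3,
                    "se_ms": None if not np.isfinite(self.tau_se[i]) else self.tau_se[i] * 1e3,
                    "k_per_s": None if not np.isfinite(self.rate[i]) else float(self.rate[i]),
                    "occupancy": float(self.occupancy[i]),
                    "level_pA": float(self.level_means[i] * 1e12),
                    "n_events": int(self.n_events[i]),
                }
                for i in range(self.n_states)
            ],
            "transition_probs": self.transition_probs.tolist(),
            "transition_counts": self.transition_counts.astype(int).tolist(),
            "occupancy": clean(self.occupancy),
        }


def kinetics_summary(
    events: Sequence[DwellEvent],
    ideal: IdealizedTrace,
    bias: float,
    dead_time: float = 0.0,
    censored_mode: str = "drop",
) -> KineticsSummary:
    """Aggregate dwell events and a state sequence into kinetic estimates.

    Occupancy is computed from the per-sample assignment (all samples,
    censored spans included), which matches the fraction-of-time meaning
    and is robust to edge censoring.  A state with too few dwells gets
    tau = NaN but still contributes occupancy.
    """
    if not events:
        raise ValueError("no events")
    k = ideal.n_states
    tau = np.full(k, np.nan)
    se = np.full(k, np.nan)
    n_events = np.zeros(k, dtype=int)
    for s in range(k):
        durs = np.array([e.t_D for e in events if e.state == s])
        cens = np.array([e.censored for e in events if e.state == s], bool)
        n_events[s] = durs.size
        try:
            fit = fit_dwell_mle(durs, cens, dead_time, censored_mode)
        except ValueError:
            continue
        tau[s], se[s] = fit.tau, fit.se

    counts = np.bincount(ideal.state_seq, minlength=k).astype(float)
    occupancy = counts / counts.sum()

    trans_counts = np.zeros((k, k))
    seq_states = np.array([e.state for e in events])
    for a, b in zip(seq_states[:-1], seq_states[1:]):
        trans_counts[a, b] += 1
    trans_probs = np.zeros_like(trans_counts)
    row = trans_counts.sum(axis=1)
    nz = row > 0
    trans_probs[nz] = trans_counts[nz] / row[nz, None]

    with np.errstate(divide="ignore", invalid="ignore"):
        rate = 1.0 / tau
    return KineticsSummary(
        tau=tau,
        tau_se=se,
        rate=rate,
        occupancy=occupancy,
        transition_counts=trans_counts,
        transition_probs=trans_probs,
        n_events=n_events,
        level_means=ideal.level_means.copy(),
        bias=bias,
        dead_time=dead_time,
    )


@dataclass(frozen=True)
class BiasSeries:
    """Kinetic summaries across applied biases (one summary per bias)."""

    summaries: list[KineticsSummary] = field(default_factory=list)

    def __post_init__(self) -> None:
        biases = [s.bias for s in self.summaries]
        if len(set(biases)) != len(biases):
            raise ValueError("biases must be distinct")

    @property
    def biases(self) -> np.ndarray:
        return np.array([s.bias for s in self.summaries])

    def conductances(self, state: int) -> np.ndarray:
        return np.array([s.conductance[state] for s in self.summaries])


def conductance_vs_bias(
    series: BiasSeries, state: int, window: tuple[float, float]
) -> tuple[float, float, float]:
    """OLS fit of a state's chord conductance against bias over a window.

    Returns (slope in S/V, intercept in S, r^2).
    """
    biases = series.biases
    mask = (biases >= min(window)) & (biases <= max(window))
    if mask.sum() < 3:
        raise ValueError("need at least 3 biases inside the window")
    g = series.conductances(state)[mask]
    res = stats.linregress(biases[mask], g)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def conductance_ratio(
    g_strep: np.ndarray, g_biotin: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-bias conductance ratio of bridged vs biotin-only junctions.

    Returns the ratio array and its coefficient of variation (sample
    sd / mean) across biases, quantifying how flat the ratio stays.
    """
    gs = np.atleast_1d(np.asarray(g_strep, float))
    gb = np.atleast_1d(np.asarray(g_biotin, float))
    if np.any(gb <= 0):
        raise ValueError("baseline conductance must be > 0")
    ratio = gs / gb
    cv = 0.0 if ratio.size < 2 else float(ratio.std(ddof=1) / ratio.mean())
    return ratio, cv


def protein_conductance(sweep_strep: IVSweep, sweep_biotin: IVSweep) -> tuple[np.ndarray, np.ndarray]:
    """Per-bias protein conductance from the bridged-minus-biotin current.

    G_protein(V) = (I_strep - I_biotin) / V; at V = 0 the chord is
    replaced by the two-sided finite-difference slope of the current
    difference.  The biotin sweep is interpolated onto the bridged
    sweep's grid when the grids differ.
    """
    v = sweep_strep.bias
    ib = sweep_biotin.current
    if not np.array_equal(sweep_biotin.bias, v):
        lo = max(v.min(), sweep_biotin.bias.min())
        hi = min(v.max(), sweep_biotin.bias.max())
        if lo >= hi:
            raise ValueError("sweep bias grids do not overlap")
        keep = (v >= lo) & (v <= hi)
        v = v[keep]
        order = np.argsort(sweep_biotin.bias)
        ib = np.interp(v, sweep_biotin.bias[order], sweep_biotin.current[order])
        di = sweep_strep.current[keep] - ib
    else:
        di = sweep_strep.current - ib

    with np.errstate(divide="ignore", invalid="ignore"):
        g = di / v
    zero = v == 0
    if np.any(zero):
        g[zero] = np.gradient(di, v)[zero]
    return v, g


def probe_yield(n_success: int, n_total: int) -> tuple[float, int]:
    """Success percentage (exact and rounded half-away-from-zero)."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not (0 <= n_success <= n_total):
        raise ValueError("n_success must lie in [0, n_total]")
    pct = 100.0 * n_success / n_total
    return pct, int(np.floor(pct + 0.5))
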