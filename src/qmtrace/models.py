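"""Core containers for tunneling-junction trace analysis.

All quantities are SI internally (amperes, volts, seconds, siemens,
meters).  Helper constructors accept the bench units used at the rig
(pA, mV, ms, nS) and convert.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "StateModel",
    "AcquisitionConfig",
    "GroundTruthLog",
    "TimeTrace",
    "IVSweep",
    "DwellEvent",
    "default_transition_matrix",
]


def default_transition_matrix(n_states: int) -> np.ndarray:
    """Embedded jump matrix encoding the observed transition ranking.

    For the four-state junction the interconversion S1<->S2 dominates,
    S2<->S3 is next, and S2<->S4 is rarest; off-diagonal weights
    0.7/0.2/0.1 reproduce that ordering.  Two- and three-state variants
    follow the same nearest-level preference; other sizes fall back to a
    uniform off-diagonal matrix.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if n_states == 1:
        return np.zeros((1, 1))
    if n_states == 2:
        return np.array([[0.0, 1.0], [1.0, 0.0]])
    if n_states == 3:
        return np.array(
            [
                [0.0, 0.7, 0.3],
                [0.7, 0.0, 0.3],
                [0.3, 0.7, 0.0],
            ]
        )
    if n_states == 4:
        return np.array(
            [
                [0.0, 0.7, 0.2, 0.1],
                [0.7, 0.0, 0.2, 0.1],
                [0.2, 0.7, 0.0, 0.1],
                [0.2, 0.7, 0.1, 0.0],
            ]
        )
    mat = np.full((n_states, n_states), 1.0 / (n_states - 1))
    np.fill_diagonal(mat, 0.0)
    return mat


@dataclass(frozen=True)
class StateModel:
    """N-state switching model: conductance levels + semi-Markov kinetics.

    Parameters
    ----------
    levels
        Per-state mean current at the trace bias, amperes, strictly
        increasing (state 0 is the lowest level, labelled S1).
    mean_dwells
        Per-state mean dwell time tau_i, seconds.
    transition_probs
        Embedded jump matrix: row i is the distribution of the successor
        state given a departure from state i (zero diagonal).  Defaults
        to :func:`default_transition_matrix`.
    """

    levels: np.ndarray
    mean_dwells: np.ndarray
    transition_probs: np.ndarray | None = None

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, dtype=float)
        dwells = np.asarray(self.mean_dwells, dtype=float)
        if levels.ndim != 1 or levels.size < 1:
            raise ValueError("levels must be a non-empty 1-D array")
        if dwells.shape != levels.shape:
            raise ValueError("mean_dwells must match levels in shape")
        if np.any(dwells <= 0):
            raise ValueError("all mean dwell times must be > 0")
        if levels.size > 1 and np.any(np.diff(levels) <= 0):
            raise ValueError("levels must be strictly increasing")
        tp = self.transition_probs
        if tp is None:
            tp = default_transition_matrix(levels.size)
        tp = np.asarray(tp, dtype=float)
        if tp.shape != (levels.size, levels.size):
            raise ValueError("transition_probs must be (n_states, n_states)")
        if np.any(np.abs(np.diagonal(tp)) > 0):
            raise ValueError("transition_probs diagonal must be zero")
        if np.any(tp < 0):
            raise ValueError("transition_probs must be non-negative")
        if levels.size > 1 and not np.allclose(tp.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each transition_probs row must sum to 1")
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "mean_dwells", dwells)
        object.__setattr__(self, "transition_probs", tp)

    @property
    def n_states(self) -> int:
        return int(self.levels.size)

    @classmethod
    def from_bench_units(
        cls,
        levels_pA: "np.ndarray | list[float]",
        tau_ms: "np.ndarray | list[float]",
        transition_probs: np.ndarray | None = None,
    ) -> "StateModel":
        return cls(
            levels=np.asarray(levels_pA, float) * 1e-12,
            mean_dwells=np.asarray(tau_ms, float) * 1e-3,
            transition_probs=transition_probs,
        )

    def stationary_occupancy(self) -> np.ndarray:
        """Long-run fraction of time per state (semi-Markov stationary law).

        The embedded chain's stationary vector nu is weighted by the mean
        dwell: p_i proportional to nu_i * tau_i.  For a two-state model this
        reduces to the alternating-renewal result tau_1/(tau_1+tau_2).
        """
        if self.n_states == 1:
            return np.array([1.0])
        vals, vecs = np.linalg.eig(self.transition_probs.T)
        idx = int(np.argmin(np.abs(vals - 1.0)))
        nu = np.real(vecs[:, idx])
        nu = np.abs(nu) / np.abs(nu).sum()
        p = nu * self.mean_dwells
        return p / p.sum()


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition chain settings for rendering a synthetic recording.

    Defaults mirror a patch-clamp style rig: 100 kHz sampling
    (``sample_interval`` = 10 us) with a 4-pole low-pass Bessel filter at
    10 kHz.  ``filter_cutoff=None`` disables filtering.  ``noise_sigma``
    is the white Gaussian noise sd before filtering; ``pink_amplitude``
    sets the 1/f component so its one-sided PSD is ``pink_amplitude**2 / f``
    (amperes at the 1 Hz reference).
    """

    duration: float
    sample_interval: float = 1e-5
    filter_cutoff: float | None = 1e4
    filter_poles: int = 4
    noise_sigma: float = 0.0
    pink_amplitude: float = 0.0
    bias: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        nyquist = 0.5 / self.sample_interval
        if self.filter_cutoff is not None and not (0 < self.filter_cutoff < nyquist):
            raise ValueError(
                f"filter_cutoff must lie in (0, {nyquist:g} Hz); got {self.filter_cutoff}"
            )
        if self.noise_sigma < 0 or self.pink_amplitude < 0:
            raise ValueError("noise amplitudes must be >= 0")

    @property
    def n_samples(self) -> int:
        # tolerate float representation of duration/dt ratios (10.0/1e-5)
        return int(np.floor(self.duration / self.sample_interval + 1e-9))


@dataclass(frozen=True)
class GroundTruthLog:
    """Event log of a simulated switching path (the simulation's truth).

    Events are contiguous and non-overlapping; durations sum to the
    requested trace duration.  The final dwell is truncated at the trace
    end and flagged censored.
    """

    states: np.ndarray
    starts: np.ndarray
    durations: np.ndarray
    censored: np.ndarray
    levels_used: np.ndarray | None = None

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=np.int64)
        starts = np.asarray(self.starts, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        censored = np.asarray(self.censored, dtype=bool)
        n = states.size
        if not (starts.size == durations.size == censored.size == n):
            raise ValueError("event arrays must share length")
        if n == 0:
            raise ValueError("log must contain at least one event")
        if np.any(durations <= 0):
            raise ValueError("durations must be > 0")
        ends = starts + durations
        if not np.allclose(ends[:-1], starts[1:], rtol=0, atol=1e-12):
            raise ValueError("events must be contiguous and non-overlapping")
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "durations", durations)
        object.__setattr__(self, "censored", censored)

    @property
    def n_events(self) -> int:
        return int(self.states.size)

    @property
    def duration(self) -> float:
        return float(self.starts[-1] + self.durations[-1])

    def state_at(self, times: np.ndarray) -> np.ndarray:
        """State index active at each query time (right-open intervals)."""
        t = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.starts, t, side="right") - 1
        idx = np.clip(idx, 0, self.n_events - 1)
        return self.states[idx]


@dataclass(frozen=True)
class TimeTrace:
    """Uniformly sampled current record at a fixed applied bias."""

    current: np.ndarray
    sample_interval: float
    bias: float = 0.0
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        current = np.asarray(self.current, dtype=float)
        if current.ndim != 1 or current.size < 2:
            raise ValueError("trace needs at least 2 samples")
        if not np.all(np.isfinite(current)):
            raise ValueError("trace contains non-finite samples")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be > 0")
        object.__setattr__(self, "current", current)

    @property
    def n_samples(self) -> int:
        return int(self.current.size)

    @property
    def duration(self) -> float:
        return self.n_samples * self.sample_interval

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sample_interval


@dataclass(frozen=True)
class IVSweep:
    """Current-bias sweep: current sampled on a strictly monotone bias grid."""

    bias: np.ndarray
    current: np.ndarray
    sweep_rate: float = 0.8

    def __post_init__(self) -> None:
        bias = np.asarray(self.bias, dtype=float)
        current = np.asarray(self.current, dtype=float)
        if bias.size != current.size:
            raise ValueError("bias and current must have equal length")
        if bias.size < 5:
            raise ValueError("sweep needs at least 5 points")
        diffs = np.diff(bias)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("bias grid must be strictly monotone")
        object.__setattr__(self, "bias", bias)
        object.__setattr__(self, "current", current)

    @property
    def n_points(self) -> int:
        return int(self.bias.size)


@dataclass(frozen=True)
class DwellEvent:
    """One uninterrupted visit to a conductance state.

    ``censored`` marks events touching a trace edge; their full duration
    is unknown and lifetime fits drop them by default.
    """

    state: int
    start: float
    t_D: float
    censored: bool = False

    def __post_init__(self) -> None:
        if self.t_D <= 0:
            raise ValueError("dwell duration must be > 0")
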