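"""Synthetic chronoamperometric traces and I-V sweeps.

The generator emulates what the bench records: an N-state semi-Markov
switching process with exponential dwells (telegraph noise), rendered as
piecewise-constant current, with white Gaussian instrument noise, an
optional 1/f (pink) component, and a causal low-pass Bessel acquisition
filter.  A :class:`~qmtrace.models.GroundTruthLog` of the switching path
is kept alongside every trace so downstream estimators can be scored by
parameter recovery.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .models import AcquisitionConfig, GroundTruthLog, IVSweep, StateModel, TimeTrace
from .simmons import SimmonsParams, simmons_current

__all__ = [
    "sample_ctmc_path",
    "render_trace",
    "simulate_trace",
    "make_pink_noise",
    "bessel_filter",
    "synth_iv_sweep",
]


def sample_ctmc_path(
    model: StateModel, duration: float, seed: int | np.random.Generator
) -> GroundTruthLog:
    """Sample a continuous-time switching path of the state model.

    Dwells in state i are exponential with mean ``tau_i``; the successor
    state is drawn from row i of the embedded jump matrix.  The initial
    state is drawn from the stationary time-fraction law so that short
    traces are not biased toward any particular start, and the dwell
    clock starts fresh at t = 0.  The final dwell is truncated at
    ``duration`` and flagged censored.

    Parameters
    ----------
    model
        State model whose invariants hold (validated at construction).
    duration
        Trace length in seconds, > 0.
    seed
        Integer seed or a ``numpy`` Generator.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    tau = model.mean_dwells
    n_states = model.n_states
    if n_states == 1:
        return GroundTruthLog(
            states=np.array([0]),
            starts=np.array([0.0]),
            durations=np.array([duration]),
            censored=np.array([True]),
            levels_used=model.levels,
        )

    cum_rows = np.cumsum(model.transition_probs, axis=1)
    state = int(rng.choice(n_states, p=model.stationary_occupancy()))

    states: list[np.ndarray] = []
    durations: list[np.ndarray] = []
    total = 0.0
    mean_cycle = float(tau.mean())
    while total < duration:
        remaining = duration - total
        chunk = max(64, int(1.3 * remaining / mean_cycle) + 16)
        chunk_states = np.empty(chunk, dtype=np.int64)
        u = rng.random(chunk)
        for j in range(chunk):
            chunk_states[j] = state
            state = int(np.searchsorted(cum_rows[state], u[j], side="right"))
        chunk_durs = rng.exponential(tau[chunk_states])
        states.append(chunk_states)
        durations.append(chunk_durs)
        total += float(chunk_durs.sum())

    all_states = np.concatenate(states)
    all_durs = np.concatenate(durations)
    ends = np.cumsum(all_durs)
    last = int(np.searchsorted(ends, duration, side="left"))
    all_states = all_states[: last + 1]
    all_durs = all_durs[: last + 1]
    starts = np.concatenate([[0.0], np.cumsum(all_durs)[:-1]])
    all_durs[-1] = duration - starts[-1]  # truncate at the trace end
    censored = np.zeros(all_states.size, dtype=bool)
    censored[-1] = True
    return GroundTruthLog(
        states=all_states,
        starts=starts,
        durations=all_durs,
        censored=censored,
        levels_used=model.levels,
    )


def make_pink_noise(
    n: int, sample_interval: float, amplitude: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Zero-mean 1/f noise by spectral shaping of seeded white noise.

    The Fourier coefficients are drawn Gaussian with variance chosen so
    the expected one-sided PSD is ``amplitude**2 / f`` over
    (1/(n*dt), Nyquist); the DC bin is zeroed.  Reproducible for a fixed
    seed.
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    if amplitude == 0:
        return np.zeros(n)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=sample_interval)
    spec = np.zeros(freqs.size, dtype=complex)
    # E|X_k|^2 = n * S(f_k) / (2 dt) reproduces S under the one-sided
    # periodogram convention S_k = 2 dt |X_k|^2 / n.
    k = np.arange(1, freqs.size)
    sigma2 = n * amplitude**2 / (2.0 * sample_interval * freqs[k])
    re = rng.standard_normal(k.size)
    im = rng.standard_normal(k.size)
    spec[k] = np.sqrt(sigma2 / 2.0) * (re + 1j * im)
    if n % 2 == 0:  # Nyquist bin of an even-length real FFT is real
        spec[-1] = spec[-1].real * np.sqrt(2.0)
    return np.fft.irfft(spec, n=n)


def bessel_filter(
    samples: np.ndarray, sample_interval: float, cutoff: float, poles: int = 4
) -> np.ndarray:
    """Causal low-pass Bessel filter (-3 dB at ``cutoff``).

    Digital approximation (bilinear transform with prewarping) of the
    analog magnitude-normalized Bessel response, applied causally as the
    acquisition hardware would.
    """
    if poles < 1:
        raise ValueError("poles must be >= 1")
    nyquist = 0.5 / sample_interval
    if not (0 < cutoff < nyquist):
        raise ValueError(f"cutoff must lie in (0, {nyquist:g} Hz); got {cutoff}")
    sos = signal.bessel(
        poles, cutoff, btype="low", norm="mag", output="sos", fs=1.0 / sample_interval
    )
    return signal.sosfilt(sos, np.asarray(samples, dtype=float))


def filter_group_delay(
    sample_interval: float, cutoff: float, poles: int = 4
) -> float:
    """Low-frequency group delay (s) of the digital Bessel filter.

    The causal acquisition filter delays every feature by this nearly
    constant lag (~3.3 samples for 4 poles at cutoff = fs/10); use it to
    align a decoded state path with simulator ground truth.
    """
    nyquist = 0.5 / sample_interval
    if not (0 < cutoff < nyquist):
        raise ValueError(f"cutoff must lie in (0, {nyquist:g} Hz); got {cutoff}")
    sos = signal.bessel(
        poles, cutoff, btype="low", norm="mag", output="sos", fs=1.0 / sample_interval
    )
    b, a = signal.sos2tf(sos)
    _, gd = signal.group_delay((b, a), w=[1e-3])
    return float(gd[0]) * sample_interval


def render_trace(
    log: GroundTruthLog, model: StateModel, acq: AcquisitionConfig
) -> TimeTrace:
    """Render a switching log into a sampled, noisy, filtered current trace.

    The clean signal is the active state's current level sampled at
    ``i * dt``; white Gaussian noise and the 1/f component are added
    before the Bessel filter, mirroring the physical signal chain.
    """
    if log.duration < acq.duration - 1e-12:
        raise ValueError("log does not cover the requested duration")
    levels = log.levels_used if log.levels_used is not None else model.levels
    levels = np.asarray(levels, dtype=float)
    if levels.size > 1 and np.any(np.diff(levels) <= 0):
        raise ValueError("level spacing must be positive")

    n = acq.n_samples
    times = np.arange(n) * acq.sample_interval
    clean = levels[log.state_at(times)]

    white_rng, pink_rng = [
        np.random.default_rng(s) for s in np.random.SeedSequence(acq.seed).spawn(2)
    ]
    x = clean
    if acq.noise_sigma > 0:
        x = x + white_rng.normal(0.0, acq.noise_sigma, n)
    if acq.pink_amplitude > 0:
        x = x + make_pink_noise(n, acq.sample_interval, acq.pink_amplitude, pink_rng)
    if acq.filter_cutoff is not None:
        x = bessel_filter(x, acq.sample_interval, acq.filter_cutoff, acq.filter_poles)
    return TimeTrace(
        current=x,
        sample_interval=acq.sample_interval,
        bias=acq.bias,
        metadata={"synthetic": True, "seed": acq.seed},
    )


def simulate_trace(
    model: StateModel, acq: AcquisitionConfig
) -> tuple[TimeTrace, GroundTruthLog]:
    """Convenience wrapper: sample a path and render it in one call."""
    path_rng = np.random.default_rng(np.random.SeedSequence(acq.seed).spawn(3)[2])
    log = sample_ctmc_path(model, acq.duration, path_rng)
    return render_trace(log, model, acq), log


def synth_iv_sweep(
    params: SimmonsParams,
    bias_grid: np.ndarray,
    sweep_rate: float = 0.8,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    transient_log: GroundTruthLog | None = None,
    transient_conductances: np.ndarray | None = None,
) -> IVSweep:
    """Synthesize an I-V sweep from a Simmons tunneling baseline.

    Optionally superimposes switching transients: with a
    ``transient_log`` and per-state excess conductances (state 0 = bare
    junction, 0 S), each grid point receives the extra ohmic current of
    the state active at the sweep time ``|V - V_0| / sweep_rate``,
    emulating the bias-dependent current steps seen when a molecule
    bridges the gap mid-sweep.
    """
    grid = np.asarray(bias_grid, dtype=float)
    current = simmons_current(params, grid)
    if transient_log is not None:
        if transient_conductances is None:
            raise ValueError("transient_conductances required with transient_log")
        g = np.asarray(transient_conductances, dtype=float)
        t = np.abs(grid - grid[0]) / sweep_rate
        current = current + g[transient_log.state_at(t)] * grid
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        current = current + rng.normal(0.0, noise_sigma, grid.size)
    return IVSweep(bias=grid, current=current, sweep_rate=sweep_rate)
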