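"""Power-spectral-density estimation and 1/f quantification.

Welch-averaged periodograms (Hann window, 50% overlap) with a
Parseval-consistent one-sided density normalization; the low-frequency
1/f component is quantified by the log-log slope of power against
frequency over a chosen band, and band-integrated power ratios compare
recordings (e.g. before vs after a molecule bridges the junction).
Absolute levels depend on windowing conventions, so comparisons are
ratio- and slope-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .models import TimeTrace

__all__ = ["PSDResult", "welch_psd", "fit_pink_slope", "psd_compare"]


@dataclass(frozen=True)
class PSDResult:
    """One-sided PSD: frequencies (Hz, DC excluded) and power (A^2/Hz)."""

    freqs: np.ndarray
    power: np.ndarray
    segment_length: int
    n_segments: int

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, float)
        p = np.asarray(self.power, float)
        if f.size != p.size or f.size < 2:
            raise ValueError("freqs and power must share length >= 2")
        if f[0] <= 0 or np.any(np.diff(f) <= 0):
            raise ValueError("freqs must be strictly increasing and > 0")
        if np.any(p < 0):
            raise ValueError("power must be >= 0")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "power", p)


def welch_psd(
    trace: TimeTrace,
    segment_length: int | None = None,
    overlap_fraction: float = 0.5,
) -> PSDResult:
    """Welch PSD of a current trace (Hann window, density scaling).

    ``segment_length`` defaults to min(2^17, trace length): at 100 kHz
    sampling this gives sub-Hz resolution, enough to resolve the
    f < 10 Hz band where binding dynamics show up.  The integral of the
    returned density approximates the sample variance (Parseval).
    """
    n = trace.n_samples
    if segment_length is None:
        segment_length = min(1 << 17, n)
    if segment_length > n:
        raise ValueError("segment_length exceeds trace length")
    if not (0 <= overlap_fraction < 1):
        raise ValueError("overlap_fraction must lie in [0, 1)")
    noverlap = int(segment_length * overlap_fraction)
    freqs, power = signal.welch(
        trace.current,
        fs=1.0 / trace.sample_interval,
        window="hann",
        nperseg=segment_length,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
    )
    step = segment_length - noverlap
    n_segments = 1 + (n - segment_length) // step if n >= segment_length else 0
    keep = freqs > 0
    return PSDResult(
        freqs=freqs[keep],
        power=power[keep],
        segment_length=int(segment_length),
        n_segments=int(n_segments),
    )


def fit_pink_slope(
    psd: PSDResult, band: tuple[float, float]
) -> tuple[float, float]:
    """Least-squares line of log10(power) on log10(frequency) over a band.

    A slope near -1 is the 1/f signature.  Returns (slope, intercept);
    the intercept is log10 power at 1 Hz.
    """
    lo, hi = band
    mask = (psd.freqs >= lo) & (psd.freqs <= hi) & (psd.power > 0)
    if mask.sum() < 5:
        raise ValueError("need at least 5 positive-power bins inside the band")
    slope, intercept = np.polyfit(
        np.log10(psd.freqs[mask]), np.log10(psd.power[mask]), 1
    )
    return float(slope), float(intercept)


def psd_compare(
    before: PSDResult, after: PSDResult, band: tuple[float, float]
) -> float:
    """Ratio of band-integrated power, after / before.

    PSDs on different grids are interpolated onto the 'before' grid
    inside the band before trapezoidal integration.
    """
    lo, hi = band
    mask = (before.freqs >= lo) & (before.freqs <= hi)
    if mask.sum() < 2:
        raise ValueError("band contains fewer than 2 frequency bins")
    f = before.freqs[mask]
    p_before = before.power[mask]
    if np.array_equal(after.freqs, before.freqs):
        p_after = after.power[mask]
    else:
        if f[0] < after.freqs[0] or f[-1] > after.freqs[-1]:
            raise ValueError("band not covered by the 'after' PSD grid")
        p_after = np.interp(f, after.freqs, after.power)
    denom = np.trapezoid(p_before, f)
    if denom <= 0:
        raise ValueError("zero integrated power in 'before' band")
    return float(np.trapezoid(p_after, f) / denom)
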