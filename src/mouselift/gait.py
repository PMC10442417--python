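"""Treadmill gait measurements from reconstructed foot trajectories.

On a treadmill running at a known belt speed, stride length is stride
duration times belt speed.  Two estimators are provided: an aggregate
estimate taking the stride frequency as the dominant peak of the foot
position's Fourier magnitude spectrum (robust, uses the whole trace), and
individual strides from peak-to-peak times in the time domain.  Individual
stride lengths far from the mean (beyond a sigma multiple, default 2.3) are
flagged as outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

__all__ = [
    "FootTrace",
    "StrideResult",
    "NoGaitError",
    "detrend_trace",
    "aggregate_stride",
    "individual_strides",
    "exclude_outliers",
]

DEFAULT_OUTLIER_SIGMA = 2.3
MIN_SEARCH_HZ = 1.0  # spectral peak search floor, excludes slow drift


class NoGaitError(ValueError):
    """No periodic structure found in the foot trace."""


@dataclass
class FootTrace:
    """Foot position along the motion axis, sampled at ``fps`` Hz."""

    samples: np.ndarray
    fps: float
    joint_name: str = "left_ankle"
    detrended: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fps

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fps


@dataclass
class StrideResult:
    aggregate_stride_length_mm: float
    peak_frequency_hz: float
    individual_durations_s: np.ndarray
    individual_lengths_mm: np.ndarray
    peak_indices: np.ndarray
    outlier_mask: np.ndarray
    outlier_sigma_used: float


def detrend_trace(trace: FootTrace, window_s: float = 1.0) -> FootTrace:
    """Remove a moving-average baseline (default 1 s window).

    Takes out slow drift and the constant offset so the spectral peak
    reflects the stride oscillation rather than posture changes.
    """
    if trace.samples.size < 4:
        raise ValueError("trace too short to detrend")
    win = max(3, int(round(window_s * trace.fps)))
    baseline = uniform_filter1d(trace.samples, size=win, mode="nearest")
    return replace(trace, samples=trace.samples - baseline, detrended=True)


def _spectral_peak(samples: np.ndarray, fps: float) -> float:
    """Dominant frequency in [MIN_SEARCH_HZ, fps/2), quadratically refined."""
    n = samples.size
    spectrum = np.abs(np.fft.rfft(samples - samples.mean()))
    freqs = np.fft.rfftfreq(n, d=1.0 / fps)
    band = (freqs >= MIN_SEARCH_HZ) & (freqs < fps / 2.0)
    if not band.any():
        raise NoGaitError("no spectral band available above 1 Hz")
    mag = spectrum[band]
    total = np.linalg.norm(samples - samples.mean())
    floor = np.median(mag)
    peak = int(np.argmax(mag))
    if total < 1e-12 or mag[peak] < 4.0 * max(floor, 1e-12):
        raise NoGaitError("no spectral peak above the noise floor")
    idx = np.flatnonzero(band)[peak]
    # quadratic interpolation around the peak bin
    if 0 < idx < spectrum.size - 1:
        a, b, c = spectrum[idx - 1], spectrum[idx], spectrum[idx + 1]
        denom = a - 2 * b + c
        delta = 0.5 * (a - c) / denom if abs(denom) > 1e-15 else 0.0
        delta = np.clip(delta, -0.5, 0.5)
    else:
        delta = 0.0
    return float((idx + delta) * fps / n)


def aggregate_stride(trace: FootTrace,
                     belt_speed: float) -> tuple[float, float]:
    """Aggregate stride estimate from the Fourier spectrum peak.

    Returns ``(peak_frequency_hz, stride_length_mm)`` where the stride
    length is belt speed divided by the peak frequency (the belt distance
    travelled per stride cycle).  Requires at least two seconds of signal.
    """
    if trace.duration_s < 2.0:
        raise ValueError("need at least 2 s of trace for spectral analysis")
    samples = trace.samples if trace.detrended else \
        detrend_trace(trace).samples
    f_peak = _spectral_peak(samples, trace.fps)
    return f_peak, float(belt_speed / f_peak)


def individual_strides(trace: FootTrace, belt_speed: float,
                       outlier_sigma: float = DEFAULT_OUTLIER_SIGMA,
                       min_prominence_sd: float = 0.25) -> StrideResult:
    """Per-stride durations and lengths from peak-to-peak times.

    Peaks need a prominence of ``min_prominence_sd`` trace standard
    deviations and a separation of at least half the aggregate stride
    period (so noise wiggles within one cycle are not counted as strides).
    """
    work = trace if trace.detrended else detrend_trace(trace)
    f_peak, agg_len = aggregate_stride(work, belt_speed)
    sd = float(np.std(work.samples))
    min_dist = max(1, int(round(0.5 / f_peak * work.fps)))
    peaks, _ = find_peaks(work.samples, prominence=min_prominence_sd * sd,
                          distance=min_dist)
    if peaks.size < 2:
        raise NoGaitError("fewer than 2 stride peaks detected")
    durations = np.diff(peaks) / work.fps
    lengths = durations * belt_speed
    _, excluded_idx = exclude_outliers(lengths, sigma=outlier_sigma)
    mask = np.zeros(lengths.size, dtype=bool)
    mask[excluded_idx] = True
    return StrideResult(
        aggregate_stride_length_mm=agg_len,
        peak_frequency_hz=f_peak,
        individual_durations_s=durations,
        individual_lengths_mm=lengths,
        peak_indices=peaks,
        outlier_mask=mask,
        outlier_sigma_used=outlier_sigma,
    )


def exclude_outliers(values: Sequence[float],
                     sigma: float = DEFAULT_OUTLIER_SIGMA
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass sigma-clipping about the sample mean.

    Mean and standard deviation are computed once from all values; entries
    with ``|x - mean| > sigma * SD`` are excluded.  Returns ``(kept_values,
    excluded_indices)``.  With zero variance nothing is excluded.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("need at least 3 values for outlier screening")
    sd = float(np.std(x, ddof=1))
    if sd == 0 or not np.isfinite(sigma):
        return x.copy(), np.empty(0, dtype=int)
    dev = np.abs(x - x.mean())
    excluded = np.flatnonzero(dev > sigma * sd)
    kept = np.delete(x, excluded)
    return kept, excluded
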