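"""The two component spindle detectors.

Both detectors use relative, data-driven thresholds computed per channel
over the analyzed window:

* Morlet route: magnitude of a complex Morlet convolution of the raw
  signal, moving-average smoothed, thresholded at a multiple of the
  envelope median.
* RMS route: band-pass 11-16 Hz, sliding-window RMS, thresholded at a
  percentile of the RMS series.

Supra-threshold runs closer than the merge gap are joined, then events
outside the duration bounds are discarded (over-long runs are dropped,
not truncated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import RmsConfig, RunConfig, WaveletConfig
from .model import EventSet, SpindleEvent, validate_set
from .preprocess import bandpass

__all__ = [
    "EnvelopeSeries",
    "morlet_envelope",
    "rms_series",
    "detect_wavelet",
    "detect_rms",
]


@dataclass(frozen=True)
class EnvelopeSeries:
    """Nonnegative envelope samples with their own rate and time origin."""

    values: np.ndarray
    rate: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.size and v.min() < 0:
            raise ValueError("envelope values must be nonnegative")
        if self.rate <= 0:
            raise ValueError("envelope rate must be positive")

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.values.size) / self.rate


def _morlet_kernel(rate: float, center_freq_hz: float, n_cycles: float) -> np.ndarray:
    """Complex Morlet: Gaussian-windowed exponential, sigma_t = n_cycles/(2*pi*f)."""
    sigma_t = n_cycles / (2.0 * np.pi * center_freq_hz)
    half = int(np.ceil(4.0 * sigma_t * rate))
    t = np.arange(-half, half + 1) / rate
    kernel = np.exp(2j * np.pi * center_freq_hz * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    return kernel / np.sum(np.abs(kernel))


def morlet_envelope(
    signal: np.ndarray,
    rate: float,
    params: WaveletConfig | None = None,
    t0_s: float = 0.0,
) -> EnvelopeSeries:
    """Magnitude of the complex-Morlet convolution, moving-average smoothed."""
    params = params or WaveletConfig()
    x = np.asarray(signal, dtype=float)
    kernel = _morlet_kernel(rate, params.center_freq_hz, params.n_cycles)
    if x.size < kernel.size:
        raise ValueError(
            f"signal ({x.size} samples) shorter than one wavelet support ({kernel.size})"
        )
    env = np.abs(sps.fftconvolve(x, kernel, mode="same"))
    win = max(1, int(round(params.smooth_win_s * rate)))
    if win > 1:
        env = np.convolve(env, np.ones(win) / win, mode="same")
    return EnvelopeSeries(values=env, rate=rate, t0_s=t0_s)


def rms_series(
    filtered_signal: np.ndarray,
    rate: float,
    window_s: float = 0.25,
    step_s: float = 0.1,
    t0_s: float = 0.0,
) -> EnvelopeSeries:
    """Sliding-window RMS of an (already band-passed) signal.

    Timestamps sit at window centers; the series rate is ``1/step_s``.
    """
    x = np.asarray(filtered_signal, dtype=float)
    win = int(round(window_s * rate))
    step = max(1, int(round(step_s * rate)))
    if win <= 0:
        raise ValueError("window_s must be positive")
    if win > x.size:
        raise ValueError(f"window ({win} samples) longer than signal ({x.size})")
    starts = np.arange(0, x.size - win + 1, step)
    sq = np.concatenate([[0.0], np.cumsum(x**2)])
    vals = np.sqrt((sq[starts + win] - sq[starts]) / win)
    return EnvelopeSeries(
        values=vals, rate=rate / step, t0_s=t0_s + (win / 2) / rate
    )


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index pairs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def _merge_and_filter(
    intervals: list[tuple[float, float]],
    merge_gap_s: float,
    min_dur_s: float,
    max_dur_s: float,
) -> list[tuple[float, float]]:
    """Join intervals separated by < merge_gap_s, then keep only those with
    duration in [min_dur_s, max_dur_s]."""
    if not intervals:
        return []
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s - merged[-1][1] < merge_gap_s:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [
        (s, e) for s, e in merged if min_dur_s <= e - s <= max_dur_s
    ]


def detect_wavelet(
    signal: np.ndarray,
    rate: float,
    config: RunConfig | None = None,
    channel: str = "C3",
    t0_s: float = 0.0,
) -> EventSet:
    """Morlet-envelope detector: runs above ``threshold_multiplier x median``."""
    config = config or RunConfig()
    p = config.wavelet
    env = morlet_envelope(signal, rate, p, t0_s=t0_s)
    med = float(np.median(env.values))
    thresh = p.threshold_multiplier * med
    mask = env.values > thresh
    intervals = [
        (t0_s + i0 / rate, t0_s + i1 / rate) for i0, i1 in _runs_above(mask)
    ]
    kept = _merge_and_filter(intervals, p.merge_gap_s, config.min_dur_s, config.max_dur_s)
    return validate_set(
        SpindleEvent(channel=channel, onset_s=s, offset_s=e, source="wavelet")
        for s, e in kept
    )


def detect_rms(
    signal: np.ndarray,
    rate: float,
    config: RunConfig | None = None,
    channel: str = "C3",
    t0_s: float = 0.0,
) -> EventSet:
    """RMS detector: band-pass, sliding RMS, percentile threshold."""
    config = config or RunConfig()
    p = config.rms
    filt = bandpass(signal, rate, config.band_low_hz, config.band_high_hz)
    series = rms_series(filt, rate, p.window_s, p.step_s, t0_s=t0_s)
    thresh = float(np.percentile(series.values, p.percentile))
    mask = series.values > thresh
    centers = series.times()
    half = p.window_s / 2.0
    intervals = [
        (centers[i0] - half, centers[i1 - 1] + half) for i0, i1 in _runs_above(mask)
    ]
    kept = _merge_and_filter(intervals, p.merge_gap_s, config.min_dur_s, config.max_dur_s)
    return validate_set(
        SpindleEvent(channel=channel, onset_s=s, offset_s=e, source="rms")
        for s, e in kept
    )
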