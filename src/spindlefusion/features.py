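"""Spindle characteristics: density, peak-to-peak amplitude, FFT mean
frequency, fixed-bin histograms, symmetric-channel counts."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps

from .model import EventSet, Recording, SpindleEvent
from .preprocess import bandpass

__all__ = [
    "FeatureSummary",
    "FREQ_BIN_EDGES",
    "AMP_BIN_EDGES",
    "density",
    "amplitude_pp",
    "mean_frequency",
    "histograms",
    "symmetric_counts",
    "summarize",
]

#: five 1-Hz frequency bands over the sigma range; last band closed at 16
FREQ_BIN_EDGES = (11.0, 12.0, 13.0, 14.0, 15.0, 16.0)
#: eight amplitude bins: seven 10-uV bins plus an open-ended last bin
AMP_BIN_EDGES = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, np.inf)

WHOLE_NIGHT_MIN = 480.0

_PAD_S = 0.5  # filtering context around an event, trimmed before measuring


@dataclass(frozen=True)
class FeatureSummary:
    subject_id: str
    channel: str
    n_spindles: int
    density_per_min: float
    mean_amplitude_uV: float
    mean_frequency_hz: float
    frequency_histogram: tuple[float, ...]
    amplitude_histogram: tuple[float, ...]


def density(n_spindles: int, minutes: float) -> float:
    """Spindles per minute of sleep."""
    if minutes <= 0:
        raise ValueError(f"minutes must be positive, got {minutes}")
    if n_spindles < 0:
        raise ValueError("n_spindles must be >= 0")
    return n_spindles / minutes


def _event_segment(recording: Recording, event: SpindleEvent) -> tuple[np.ndarray, int, int]:
    """Band-pass-ready padded samples plus the event's slice within them."""
    rate = recording.sampling_rate
    sig = recording.channel(event.channel)
    i0 = int(np.floor((event.onset_s - recording.start_offset_s) * rate + 0.5))
    i1 = int(np.floor((event.offset_s - recording.start_offset_s) * rate + 0.5))
    if i0 < 0 or i1 > sig.size or i1 <= i0:
        raise ValueError(
            f"event [{event.onset_s}, {event.offset_s}) s on {event.channel} "
            "lies outside the recording"
        )
    pad = int(round(_PAD_S * rate))
    j0 = max(0, i0 - pad)
    j1 = min(sig.size, i1 + pad)
    return sig[j0:j1], i0 - j0, i1 - j0


def amplitude_pp(recording: Recording, event: SpindleEvent) -> float:
    """Maximum peak-to-peak amplitude (uV) of the 11-16 Hz band-passed
    event segment; 0.5 s of context on each side is filtered along with
    the event and trimmed before measuring."""
    seg, a, b = _event_segment(recording, event)
    filt = bandpass(seg, recording.sampling_rate)
    within = filt[a:b]
    return float(within.max() - within.min())


def mean_frequency(recording: Recording, event: SpindleEvent) -> float:
    """Power-weighted mean frequency (Hz) over 11-16 Hz of the event's
    detrended, Hann-windowed periodogram, zero-padded to 4 s."""
    if event.duration_s < 0.5:
        raise ValueError(f"event too short for spectral analysis ({event.duration_s} s)")
    rate = recording.sampling_rate
    seg, a, b = _event_segment(recording, event)
    x = sps.detrend(seg[a:b])
    x = x * np.hanning(x.size)
    nfft = max(int(round(4.0 * rate)), x.size)
    spec = np.abs(np.fft.rfft(x, n=nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rate)
    band = (freqs >= 11.0) & (freqs <= 16.0)
    power = spec[band]
    if power.sum() <= 0:
        raise ValueError("no sigma-band power in event segment")
    return float(np.sum(freqs[band] * power) / power.sum())


def _hist(values: Sequence[float], edges: Sequence[float], close_last: bool) -> tuple[float, ...]:
    n = len(values)
    counts = [0] * (len(edges) - 1)
    for v in values:
        for i in range(len(edges) - 1):
            hi_ok = v <= edges[i + 1] if (close_last and i == len(edges) - 2) else v < edges[i + 1]
            if edges[i] <= v and hi_ok:
                counts[i] += 1
                break
    if n == 0:
        return tuple(0.0 for _ in counts)
    return tuple(c / n for c in counts)


def histograms(
    events: Iterable[SpindleEvent],
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Proportion histograms over the fixed frequency and amplitude bins.

    Bins are left-closed/right-open; the last frequency bin is closed at
    16 Hz, the last amplitude bin is open-ended.  Empty input yields
    all-zero histograms.
    """
    evs = list(events)
    freqs = [e.mean_freq_hz for e in evs if e.mean_freq_hz is not None]
    amps = [e.amplitude_pp_uV for e in evs if e.amplitude_pp_uV is not None]
    return (
        _hist(freqs, FREQ_BIN_EDGES, close_last=True),
        _hist(amps, AMP_BIN_EDGES, close_last=False),
    )


def symmetric_counts(
    events_by_channel: dict[str, Sequence[SpindleEvent]] | EventSet,
    pairs: Sequence[tuple[str, str]] = (("C3", "C4"), ("F3", "F4")),
) -> dict[tuple[str, str], tuple[int, int, int]]:
    """Per symmetric channel pair: (count A, count B, signed difference B - A)."""
    if isinstance(events_by_channel, EventSet):
        es = events_by_channel
        events_by_channel = {ch: es.on_channel(ch) for ch in es.channels}
    out = {}
    for a, b in pairs:
        if a not in events_by_channel or b not in events_by_channel:
            raise KeyError(f"missing channel for symmetric pair ({a}, {b})")
        na, nb = len(events_by_channel[a]), len(events_by_channel[b])
        out[(a, b)] = (na, nb, nb - na)
    return out


def summarize(
    subject_id: str,
    channel: str,
    events: Iterable[SpindleEvent],
    minutes: float,
) -> FeatureSummary:
    """Per-subject per-channel feature summary from feature-bearing events."""
    evs = [e for e in events if e.channel == channel]
    freq_h, amp_h = histograms(evs)
    amps = [e.amplitude_pp_uV for e in evs if e.amplitude_pp_uV is not None]
    frqs = [e.mean_freq_hz for e in evs if e.mean_freq_hz is not None]
    return FeatureSummary(
        subject_id=subject_id,
        channel=channel,
        n_spindles=len(evs),
        density_per_min=density(len(evs), minutes),
        mean_amplitude_uV=float(np.mean(amps)) if amps else 0.0,
        mean_frequency_hz=float(np.mean(frqs)) if frqs else 0.0,
        frequency_histogram=freq_h,
        amplitude_histogram=amp_h,
    )
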