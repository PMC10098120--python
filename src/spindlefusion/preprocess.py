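"""Band-pass filtering and temporal windowing (scoring window, first sleep cycle)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .model import Hypnogram

__all__ = ["ScoringWindow", "bandpass", "scoring_window", "first_cycle"]

EIGHT_HOURS_S = 8 * 3600.0
NREM = ("N1", "N2", "N3")


@dataclass(frozen=True)
class ScoringWindow:
    start_s: float
    end_s: float
    reason: str = ""

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("scoring window must have end > start")
        if self.end_s - self.start_s > EIGHT_HOURS_S + 1e-9:
            raise ValueError("scoring window exceeds 8 h")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def duration_min(self) -> float:
        return self.duration_s / 60.0


def bandpass(
    signal: np.ndarray, rate: float, low_hz: float = 11.0, high_hz: float = 16.0
) -> np.ndarray:
    """Zero-phase band-pass: 4th-order Butterworth run forward and backward.

    Output has the same length as the input.  Requires ``rate > 2*high_hz``.
    """
    if rate <= 2 * high_hz:
        raise ValueError(
            f"sampling rate {rate} Hz too low for a {high_hz} Hz band edge"
        )
    x = np.asarray(signal, dtype=float)
    sos = sps.butter(4, [low_hz, high_hz], btype="bandpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, x)


def scoring_window(
    hypnogram: Hypnogram, recording_end_s: float | None = None
) -> ScoringWindow:
    """Up to 8 h starting at the first non-wake epoch.

    ``recording_end_s`` caps the window (defaults to the hypnogram end).
    Raises on an all-wake hypnogram.
    """
    ep = hypnogram.epoch_length_s
    onset_idx = next(
        (i for i, st in enumerate(hypnogram.stages) if st != "W"), None
    )
    if onset_idx is None:
        raise ValueError("no sleep epoch in hypnogram (all wake)")
    start = onset_idx * ep
    end_cap = hypnogram.duration_s if recording_end_s is None else recording_end_s
    end = min(start + EIGHT_HOURS_S, end_cap)
    return ScoringWindow(start, end, reason="8 h from first sleep stage")


def first_cycle(hypnogram: Hypnogram) -> ScoringWindow:
    """First sleep cycle: first NREM epoch through the end of the first
    maximal contiguous REM run that begins after it."""
    ep = hypnogram.epoch_length_s
    stages = hypnogram.stages
    start_idx = next((i for i, st in enumerate(stages) if st in NREM), None)
    if start_idx is None:
        raise ValueError("first cycle incomplete: no NREM epoch")
    rem_start = next(
        (i for i in range(start_idx + 1, len(stages)) if stages[i] == "REM"), None
    )
    if rem_start is None:
        raise ValueError("first cycle incomplete: no REM after NREM")
    rem_end = rem_start
    while rem_end + 1 < len(stages) and stages[rem_end + 1] == "REM":
        rem_end += 1
    return ScoringWindow(
        start_idx * ep, (rem_end + 1) * ep, reason="first NREM to end of first REM run"
    )
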