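"""Core domain types and interval arithmetic.

Events live on a single channel and carry half-open time intervals
``[onset_s, offset_s)`` in seconds from recording start.  Touching
events do not overlap.  All other modules build on these types.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import numpy as np

__all__ = [
    "STAGES",
    "SOURCES",
    "LABELS",
    "Recording",
    "Hypnogram",
    "SpindleEvent",
    "EventSet",
    "duration",
    "overlaps",
    "overlap_fraction",
    "validate_set",
]

STAGES = ("W", "N1", "N2", "N3", "REM")
SOURCES = ("wavelet", "rms", "fusion", "expert", "truth")
LABELS = ("true", "false", "unknown")

#: analysis (sigma) band bounds in Hz
BAND_LOW_HZ = 11.0
BAND_HIGH_HZ = 16.0


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


@dataclass(frozen=True)
class SpindleEvent:
    """One detected or annotated spindle on a single channel.

    Parameters
    ----------
    channel : str
        10-20 system channel label (e.g. ``"C3"``).
    onset_s, offset_s : float
        Half-open interval bounds in seconds; ``offset_s > onset_s``.
    amplitude_pp_uV : float, optional
        Maximum peak-to-peak amplitude in microvolts; set by feature
        extraction.
    mean_freq_hz : float, optional
        Power-weighted mean frequency in Hz; must lie in the sigma band.
    source : str
        One of ``wavelet, rms, fusion, expert, truth``.
    label : str
        Truth label: ``"true"``, ``"false"`` or ``"unknown"``.
    """

    channel: str
    onset_s: float
    offset_s: float
    amplitude_pp_uV: Optional[float] = None
    mean_freq_hz: Optional[float] = None
    source: str = "truth"
    label: str = "unknown"

    def __post_init__(self) -> None:
        if not self.channel:
            raise ValidationError("event channel must be non-empty")
        if not np.isfinite(self.onset_s) or not np.isfinite(self.offset_s):
            raise ValidationError("event bounds must be finite")
        if self.offset_s <= self.onset_s:
            raise ValidationError(
                f"event offset ({self.offset_s}) must exceed onset ({self.onset_s})"
            )
        if self.amplitude_pp_uV is not None and self.amplitude_pp_uV <= 0:
            raise ValidationError("amplitude_pp_uV must be positive when set")
        if self.mean_freq_hz is not None and not (
            BAND_LOW_HZ <= self.mean_freq_hz <= BAND_HIGH_HZ
        ):
            raise ValidationError(
                f"mean_freq_hz {self.mean_freq_hz} outside analysis band "
                f"[{BAND_LOW_HZ}, {BAND_HIGH_HZ}]"
            )
        if self.source not in SOURCES:
            raise ValidationError(f"unknown source {self.source!r}")
        if self.label not in LABELS:
            raise ValidationError(f"unknown label {self.label!r}")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    def with_features(
        self, amplitude_pp_uV: float, mean_freq_hz: float
    ) -> "SpindleEvent":
        return replace(
            self, amplitude_pp_uV=amplitude_pp_uV, mean_freq_hz=mean_freq_hz
        )


def duration(e: SpindleEvent) -> float:
    """Event duration in seconds (``offset - onset``, always > 0)."""
    return e.offset_s - e.onset_s


def overlaps(a: SpindleEvent, b: SpindleEvent) -> bool:
    """True iff the half-open intervals of two same-channel events intersect."""
    if a.channel != b.channel:
        raise ValueError(
            f"overlaps() requires same-channel events, got {a.channel!r} vs {b.channel!r}"
        )
    return a.onset_s < b.offset_s and b.onset_s < a.offset_s


def overlap_fraction(a: SpindleEvent, b: SpindleEvent) -> float:
    """Length of the intersection divided by the shorter event's duration."""
    if a.channel != b.channel:
        raise ValueError(
            f"overlap_fraction() requires same-channel events, got "
            f"{a.channel!r} vs {b.channel!r}"
        )
    inter = min(a.offset_s, b.offset_s) - max(a.onset_s, b.onset_s)
    if inter <= 0:
        return 0.0
    return inter / min(duration(a), duration(b))


@dataclass(frozen=True)
class EventSet:
    """Validated, per-channel onset-ordered collection of events.

    Build instances through :func:`validate_set`; the constructor assumes
    the invariants already hold.
    """

    events: tuple[SpindleEvent, ...] = ()

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[SpindleEvent]:
        return iter(self.events)

    def __bool__(self) -> bool:
        return bool(self.events)

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(sorted({e.channel for e in self.events}))

    def on_channel(self, channel: str) -> tuple[SpindleEvent, ...]:
        return tuple(e for e in self.events if e.channel == channel)


def validate_set(events: Iterable[SpindleEvent]) -> EventSet:
    """Sort events per channel, drop exact channel+interval duplicates.

    Raises
    ------
    ValidationError
        If any entry is not a valid :class:`SpindleEvent` (construction
        already enforces per-event invariants, so only type errors can
        surface here).
    """
    evs = list(events)
    bad = [e for e in evs if not isinstance(e, SpindleEvent)]
    if bad:
        raise ValidationError(f"not SpindleEvent instances: {bad!r}")
    seen: dict[tuple[str, float, float], SpindleEvent] = {}
    for e in evs:
        key = (e.channel, e.onset_s, e.offset_s)
        if key not in seen:
            seen[key] = e
    ordered = sorted(seen.values(), key=lambda e: (e.channel, e.onset_s, e.offset_s))
    return EventSet(tuple(ordered))


@dataclass(frozen=True)
class Recording:
    """Multichannel EEG recording in microvolts.

    ``samples`` is a ``(n_channels, n_samples)`` float array aligned with
    ``channel_labels``.
    """

    subject_id: str
    channel_labels: tuple[str, ...]
    sampling_rate: float
    samples: np.ndarray
    start_offset_s: float = 0.0

    def __post_init__(self) -> None:
        labels = tuple(self.channel_labels)
        object.__setattr__(self, "channel_labels", labels)
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 2:
            raise ValidationError("samples must be a 2-D (channels x samples) array")
        object.__setattr__(self, "samples", arr)
        if len(labels) != arr.shape[0]:
            raise ValidationError(
                f"{len(labels)} labels but {arr.shape[0]} sample rows"
            )
        if len(set(labels)) != len(labels):
            raise ValidationError("channel labels must be unique")
        if self.sampling_rate < 100:
            raise ValidationError(
                f"sampling_rate {self.sampling_rate} Hz < 100 Hz (sigma band needs >= 100)"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None
        return self.samples[idx]

    def segment(self, label: str, start_s: float, end_s: float) -> np.ndarray:
        """Samples of ``label`` within ``[start_s, end_s)`` (seconds from
        recording start); indices round half away from zero."""
        sig = self.channel(label)
        i0 = _round_half_away((start_s - self.start_offset_s) * self.sampling_rate)
        i1 = _round_half_away((end_s - self.start_offset_s) * self.sampling_rate)
        i0 = max(i0, 0)
        i1 = min(i1, sig.size)
        if i1 <= i0:
            raise ValueError(
                f"segment [{start_s}, {end_s}) s lies outside the recording"
            )
        return sig[i0:i1]


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(np.floor(x + 0.5)) if x >= 0 else int(np.ceil(x - 0.5))


@dataclass(frozen=True)
class Hypnogram:
    """Per-epoch sleep-stage sequence over {W, N1, N2, N3, REM}."""

    stages: tuple[str, ...]
    epoch_length_s: float = 30.0

    def __post_init__(self) -> None:
        stages = tuple(self.stages)
        object.__setattr__(self, "stages", stages)
        if not stages:
            raise ValidationError("hypnogram must be non-empty")
        if self.epoch_length_s <= 0:
            raise ValidationError("epoch_length_s must be positive")
        unknown = sorted(set(stages) - set(STAGES))
        if unknown:
            raise ValidationError(f"unknown sleep stages: {unknown}")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_length_s
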