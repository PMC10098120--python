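"""Readers and writers: EDF recordings, CSV event lists, hypnograms,
subject tables, and YAML run configuration."""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, fields as dc_fields
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .edf import EdfSignal, read_edf, write_edf
from .model import (
    EventSet,
    Hypnogram,
    Recording,
    SpindleEvent,
    ValidationError,
    validate_set,
)

__all__ = [
    "SubjectRecord",
    "RunConfig",
    "WaveletConfig",
    "RmsConfig",
    "FusionConfig",
    "EvalConfig",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "read_hypnogram",
    "write_hypnogram",
    "read_subjects",
    "write_subjects",
    "load_config",
    "packaged_subjects",
]

GROUPS = ("DS", "NS")


@dataclass(frozen=True)
class SubjectRecord:
    """One row of the subject table (group label, PSQI, first-cycle summaries)."""

    subject_id: str
    group: str
    psqi: int
    first_cycle_min: Optional[float] = None
    first_cycle_spindles: Optional[int] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not 0 <= self.psqi <= 21:
            raise ValidationError(f"psqi {self.psqi} outside [0, 21]")
        if self.group == "DS" and self.psqi < 11:
            warnings.warn(
                f"{self.subject_id}: DS subject with PSQI {self.psqi} < 11 "
                "(contradicts the sleep-disorder cut)",
                stacklevel=2,
            )
        if self.first_cycle_min is not None and self.first_cycle_min <= 0:
            raise ValidationError("first_cycle_min must be positive when set")
        if self.first_cycle_spindles is not None and self.first_cycle_spindles < 0:
            raise ValidationError("first_cycle_spindles must be >= 0 when set")


@dataclass(frozen=True)
class WaveletConfig:
    center_freq_hz: float = 13.5
    n_cycles: float = 7.0
    smooth_win_s: float = 0.1
    # multiple of the median envelope; calibrated on the synthetic
    # operating point (background RMS 15 uV, spindles 15-60 uV pp)
    threshold_multiplier: float = 2.0
    merge_gap_s: float = 0.2


@dataclass(frozen=True)
class RmsConfig:
    window_s: float = 0.25
    step_s: float = 0.1
    percentile: float = 95.0
    merge_gap_s: float = 0.2


@dataclass(frozen=True)
class FusionConfig:
    k_min: int = 2
    k_max: int = 6
    reject_fraction: float = 0.5
    seed: int = 0


@dataclass(frozen=True)
class EvalConfig:
    match_fraction: float = 0.2
    bin_s: float = 0.5


@dataclass(frozen=True)
class RunConfig:
    """Full run configuration with validated defaults."""

    band_low_hz: float = 11.0
    band_high_hz: float = 16.0
    min_dur_s: float = 0.5
    max_dur_s: float = 3.0
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    rms: RmsConfig = field(default_factory=RmsConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)

    def __post_init__(self) -> None:
        if self.band_low_hz >= self.band_high_hz:
            raise ValidationError(
                f"band_low_hz ({self.band_low_hz}) must be < band_high_hz "
                f"({self.band_high_hz})"
            )
        if self.min_dur_s >= self.max_dur_s:
            raise ValidationError("min_dur_s must be < max_dur_s")
        for name, val in [
            ("min_dur_s", self.min_dur_s),
            ("wavelet.threshold_multiplier", self.wavelet.threshold_multiplier),
            ("wavelet.center_freq_hz", self.wavelet.center_freq_hz),
            ("wavelet.n_cycles", self.wavelet.n_cycles),
            ("rms.window_s", self.rms.window_s),
            ("rms.step_s", self.rms.step_s),
        ]:
            if val <= 0:
                raise ValidationError(f"{name} must be positive, got {val}")
        if not 0 < self.rms.percentile <= 100:
            raise ValidationError("rms.percentile must be in (0, 100]")
        if not 0 <= self.fusion.reject_fraction <= 1:
            raise ValidationError("fusion.reject_fraction must be in [0, 1]")


def _build_config(data: dict) -> RunConfig:
    sections = {"wavelet": WaveletConfig, "rms": RmsConfig,
                "fusion": FusionConfig, "evaluation": EvalConfig}
    top_keys = {f.name for f in dc_fields(RunConfig)}
    kwargs: dict = {}
    for key, value in data.items():
        if key not in top_keys:
            raise ValidationError(f"unknown config key {key!r}")
        if key in sections:
            cls = sections[key]
            valid = {f.name for f in dc_fields(cls)}
            bad = set(value) - valid
            if bad:
                raise ValidationError(f"unknown config key(s) under {key!r}: {sorted(bad)}")
            kwargs[key] = cls(**value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML :class:`RunConfig`; ``None`` returns the defaults.

    Unknown keys raise — silent typos would silently change a run.
    """
    if path is None:
        return RunConfig()
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a YAML mapping")
    return _build_config(data)


# -- recordings ---------------------------------------------------------------


def read_recording(
    path: str | Path,
    wanted_channels: Sequence[str] | None = None,
    subject_id: str | None = None,
) -> Recording:
    """Read an EDF file into a :class:`Recording` (samples in uV).

    Raises if a wanted channel is missing or the wanted channels have
    mixed sampling rates (no implicit resampling).
    """
    signals = read_edf(str(path))
    by_label = {s.label: s for s in signals}
    if wanted_channels is None:
        wanted_channels = [s.label for s in signals]
    missing = [c for c in wanted_channels if c not in by_label]
    if missing:
        raise KeyError(f"{path}: channel(s) not in file: {missing}")
    chosen = [by_label[c] for c in wanted_channels]
    rates = {s.rate for s in chosen}
    if len(rates) > 1:
        raise ValueError(
            f"{path}: mixed sampling rates across wanted channels: {sorted(rates)}"
        )
    return Recording(
        subject_id=subject_id or Path(path).stem,
        channel_labels=tuple(wanted_channels),
        sampling_rate=rates.pop(),
        samples=np.vstack([s.samples for s in chosen]),
    )


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write a :class:`Recording` to plain EDF (1 s records, uV)."""
    signals = [
        EdfSignal(label=lab, rate=recording.sampling_rate, samples=recording.samples[i])
        for i, lab in enumerate(recording.channel_labels)
    ]
    write_edf(str(path), signals, patient_id=recording.subject_id)


# -- events -------------------------------------------------------------------

_EVENT_HEADER = ["subject_id", "channel", "onset_s", "duration_s", "source", "label"]
_LABEL_IN = {"1": "true", "0": "false", "": "unknown"}
_LABEL_OUT = {"true": "1", "false": "0", "unknown": ""}


def read_events(path: str | Path) -> EventSet:
    """Read an event CSV (``subject_id,channel,onset_s,duration_s,source,label``)."""
    events = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [
            c for c in _EVENT_HEADER[:5] if c not in reader.fieldnames
        ]:
            raise ValidationError(f"{path}: missing event CSV header {_EVENT_HEADER[:5]}")
        for lineno, row in enumerate(reader, start=2):
            try:
                onset = float(row["onset_s"])
                dur = float(row["duration_s"])
                if dur <= 0:
                    raise ValidationError(f"duration_s must be > 0, got {dur}")
                label = _LABEL_IN.get((row.get("label") or "").strip())
                if label is None:
                    raise ValidationError(f"label must be '1', '0' or empty, got {row['label']!r}")
                events.append(
                    SpindleEvent(
                        channel=row["channel"],
                        onset_s=onset,
                        offset_s=onset + dur,
                        source=row["source"] or "expert",
                        label=label,
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    return validate_set(events)


def write_events(
    event_set: EventSet | Sequence[SpindleEvent],
    path: str | Path,
    subject_id: str = "",
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_EVENT_HEADER)
        for e in event_set:
            writer.writerow(
                [
                    subject_id,
                    e.channel,
                    f"{e.onset_s:.6f}",
                    f"{e.offset_s - e.onset_s:.6f}",
                    e.source,
                    _LABEL_OUT[e.label],
                ]
            )


# -- hypnograms ---------------------------------------------------------------


def read_hypnogram(path: str | Path, epoch_length_s: float = 30.0) -> Hypnogram:
    """Read a hypnogram CSV with columns ``epoch_index,stage``."""
    stages: list[tuple[int, str]] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "stage" not in reader.fieldnames:
            raise ValidationError(f"{path}: hypnogram CSV needs columns epoch_index,stage")
        for lineno, row in enumerate(reader, start=2):
            try:
                stages.append((int(row["epoch_index"]), row["stage"].strip()))
            except (ValueError, KeyError) as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    stages.sort()
    return Hypnogram(stages=tuple(s for _, s in stages), epoch_length_s=epoch_length_s)


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch_index", "stage"])
        for i, st in enumerate(hyp.stages):
            writer.writerow([i, st])


# -- subjects -----------------------------------------------------------------


def read_subjects(path: str | Path) -> list[SubjectRecord]:
    records = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        need = {"subject_id", "group", "psqi"}
        if reader.fieldnames is None or need - set(reader.fieldnames):
            raise ValidationError(f"{path}: subject CSV needs columns {sorted(need)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                fc_min = row.get("first_cycle_min")
                fc_sp = row.get("first_cycle_spindles")
                records.append(
                    SubjectRecord(
                        subject_id=row["subject_id"],
                        group=row["group"].strip(),
                        psqi=int(row["psqi"]),
                        first_cycle_min=float(fc_min) if fc_min not in (None, "") else None,
                        first_cycle_spindles=int(fc_sp) if fc_sp not in (None, "") else None,
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    return records


def write_subjects(records: Sequence[SubjectRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["subject_id", "group", "psqi", "first_cycle_min", "first_cycle_spindles"]
        )
        for r in records:
            writer.writerow(
                [
                    r.subject_id,
                    r.group,
                    r.psqi,
                    "" if r.first_cycle_min is None else r.first_cycle_min,
                    "" if r.first_cycle_spindles is None else r.first_cycle_spindles,
                ]
            )


def packaged_subjects() -> list[SubjectRecord]:
    """The bundled 30-subject table (20 DS + 10 NS) with PSQI scores and
    first-cycle durations/spindle counts."""
    ref = resources.files("spindlefusion").joinpath("data/subjects_table.csv")
    with resources.as_file(ref) as p:
        return read_subjects(p)
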