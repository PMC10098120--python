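"""Synthetic annotated-PSG cohort generator.

Produces 1/f background EEG on C3/C4/F3/F4 with embedded Hann-enveloped
spindle bursts, a simple cyclic hypnogram, group-dependent spindle
density (DS lower than NS), PSQI scores negatively coupled to density,
and three imperfect simulated annotators.  Fully deterministic under the
master seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import stats as sstats

from . import io as sio
from .model import EventSet, Hypnogram, Recording, SpindleEvent, validate_set
from .preprocess import first_cycle

__all__ = [
    "CohortParams",
    "ExpertParams",
    "gen_background",
    "gen_spindle",
    "gen_subject",
    "gen_experts",
    "gen_cohort",
    "draw_cohort_traits",
]


@dataclass(frozen=True)
class ExpertParams:
    detection_prob: float = 0.9
    amp_slope_per_uV: float = 0.05
    jitter_sd_s: float = 0.05
    false_rate_per_min: float = 0.2


@dataclass(frozen=True)
class CohortParams:
    n_ds: int = 20
    n_ns: int = 10
    sampling_rate: float = 256.0
    duration_min: float = 20.0
    channels: tuple[str, ...] = ("C3", "C4", "F3", "F4")
    background_rms_uV: float = 15.0
    spectral_alpha: float = 1.0
    # per-group spindle density ranges (events/min), uniform draws
    density_range_ds: tuple[float, float] = (0.89, 2.83)
    density_range_ns: tuple[float, float] = (1.68, 3.5)
    # spindle frequency: mixture with 70% of mass uniform on [12, 14] Hz
    freq_central_mass: float = 0.7
    duration_mean_s: float = 0.9
    duration_sd_s: float = 0.25
    duration_bounds_s: tuple[float, float] = (0.5, 1.5)
    amplitude_range_ds: tuple[float, float] = (15.0, 45.0)
    amplitude_range_ns: tuple[float, float] = (20.0, 60.0)
    # PSQI coupling: score = round(clip(a - b * density + eps))
    psqi_a: float = 22.0
    psqi_b: float = 5.5
    psqi_noise_sd: float = 1.2
    psqi_clip_ds: tuple[int, int] = (11, 21)
    psqi_clip_ns: tuple[int, int] = (0, 10)
    expert: ExpertParams = field(default_factory=ExpertParams)
    master_seed: int = 42

    def density_range(self, group: str) -> tuple[float, float]:
        return self.density_range_ds if group == "DS" else self.density_range_ns

    def amplitude_range(self, group: str) -> tuple[float, float]:
        return self.amplitude_range_ds if group == "DS" else self.amplitude_range_ns

    def psqi_clip(self, group: str) -> tuple[int, int]:
        return self.psqi_clip_ds if group == "DS" else self.psqi_clip_ns


def gen_background(
    duration_s: float,
    rate: float,
    rms_uV: float = 15.0,
    alpha: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Gaussian 1/f^alpha noise scaled to an exact overall RMS (uV)."""
    if duration_s <= 0 or rate <= 0 or rms_uV <= 0:
        raise ValueError("gen_background needs positive duration, rate and RMS")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    weights = np.ones_like(freqs)
    nz = freqs > 0
    weights[nz] = freqs[nz] ** (-alpha / 2.0)
    weights[0] = 0.0  # no DC
    x = np.fft.irfft(spectrum * weights, n=n)
    current = np.sqrt(np.mean(x**2))
    return x * (rms_uV / current)


def gen_spindle(
    freq_hz: float,
    amplitude_pp_uV: float,
    duration_s: float,
    rate: float,
    phase: float = 0.0,
) -> np.ndarray:
    """Hann-enveloped sinusoidal burst with the given peak-to-peak amplitude."""
    if not 11.0 <= freq_hz <= 16.0:
        raise ValueError(f"spindle frequency {freq_hz} Hz outside [11, 16]")
    if not 0.5 <= duration_s <= 1.5:
        raise ValueError(f"spindle duration {duration_s} s outside [0.5, 1.5]")
    if amplitude_pp_uV <= 0:
        raise ValueError("amplitude_pp_uV must be positive")
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    envelope = np.hanning(n)
    return (amplitude_pp_uV / 2.0) * envelope * np.sin(2 * np.pi * freq_hz * t + phase)


def _draw_frequency(rng: np.random.Generator, params: CohortParams, n: int = 1) -> np.ndarray:
    """Mixture: ``freq_central_mass`` uniform on [12, 14], remainder uniform
    on [11, 12) u (14, 16] proportional to width (1:2)."""
    u = rng.random(n)
    out = np.empty(n)
    central = u < params.freq_central_mass
    out[central] = rng.uniform(12.0, 14.0, central.sum())
    n_out = (~central).sum()
    side = rng.random(n_out) < (1.0 / 3.0)  # [11,12) has 1 of 3 Hz of side mass
    vals = np.where(
        side, rng.uniform(11.0, 12.0, n_out), rng.uniform(14.0, 16.0, n_out)
    )
    out[~central] = vals
    return out


def _draw_duration(rng: np.random.Generator, params: CohortParams, n: int = 1) -> np.ndarray:
    lo, hi = params.duration_bounds_s
    a = (lo - params.duration_mean_s) / params.duration_sd_s
    b = (hi - params.duration_mean_s) / params.duration_sd_s
    return sstats.truncnorm.rvs(
        a, b, loc=params.duration_mean_s, scale=params.duration_sd_s,
        size=n, random_state=rng,
    )


def _draw_psqi(rng: np.random.Generator, params: CohortParams, group: str, density: float) -> int:
    lo, hi = params.psqi_clip(group)
    raw = params.psqi_a - params.psqi_b * density + rng.normal(0.0, params.psqi_noise_sd)
    return int(np.clip(np.floor(raw + 0.5), lo, hi))


def draw_cohort_traits(
    params: CohortParams | None = None, seed: int | None = None
) -> list[tuple[str, str, float, float]]:
    """Light-weight draw of (subject_id, group, density, psqi) for the whole
    cohort without rendering any signal.

    Uses the same per-subject substreams as :func:`gen_subject`, so the
    densities and PSQI scores match a fully rendered cohort.
    """
    params = params or CohortParams()
    seed = params.master_seed if seed is None else seed
    out = []
    for sid, group, idx in _subject_plan(params):
        rng = np.random.default_rng([seed, idx, 0])
        lo, hi = params.density_range(group)
        density = rng.uniform(lo, hi)
        psqi = _draw_psqi(rng, params, group, density)
        out.append((sid, group, float(density), float(psqi)))
    return out


def _subject_plan(params: CohortParams) -> list[tuple[str, str, int]]:
    plan = [(f"DS{i + 1}", "DS", i) for i in range(params.n_ds)]
    plan += [(f"NS{i + 1}", "NS", params.n_ds + i) for i in range(params.n_ns)]
    return plan


def _cyclic_hypnogram(duration_min: float, epoch_s: float = 30.0) -> Hypnogram:
    """N1 5 min, N2 45 min, N3 20 min, REM 15 min, repeating."""
    cycle = ["N1"] * 10 + ["N2"] * 90 + ["N3"] * 40 + ["REM"] * 30
    n_epochs = int(round(duration_min * 60.0 / epoch_s))
    stages = [cycle[i % len(cycle)] for i in range(n_epochs)]
    return Hypnogram(stages=tuple(stages), epoch_length_s=epoch_s)


_GUARD_S = 0.25  # minimal spacing between placed spindles on one channel


def gen_subject(
    params: CohortParams,
    group: str,
    seed: int,
    subject_id: str | None = None,
    subject_index: int = 0,
) -> tuple[Recording, EventSet, Hypnogram, sio.SubjectRecord]:
    """Render one synthetic subject: recording, truth events, hypnogram
    and subject record (PSQI coupled negatively to density)."""
    subject_id = subject_id or f"{group}1"
    rate = params.sampling_rate
    dur_s = params.duration_min * 60.0
    n = int(round(dur_s * rate))

    trait_rng = np.random.default_rng([seed, subject_index, 0])
    lo, hi = params.density_range(group)
    density = trait_rng.uniform(lo, hi)
    psqi = _draw_psqi(trait_rng, params, group, density)

    amp_lo, amp_hi = params.amplitude_range(group)
    samples = np.empty((len(params.channels), n))
    truth: list[SpindleEvent] = []
    for ci, ch in enumerate(params.channels):
        rng = np.random.default_rng([seed, subject_index, 1 + ci])
        sig = gen_background(
            dur_s, rate, params.background_rms_uV, params.spectral_alpha, rng
        )
        n_events = rng.poisson(density * params.duration_min)
        placed: list[tuple[float, float]] = []
        for _ in range(n_events):
            d = float(_draw_duration(rng, params, 1)[0])
            for _attempt in range(1000):
                onset = rng.uniform(0.0, dur_s - d)
                if not any(
                    onset < e + _GUARD_S and s - _GUARD_S < onset + d for s, e in placed
                ):
                    break
            else:  # pragma: no cover - practically unreachable at test densities
                continue
            freq = float(_draw_frequency(rng, params, 1)[0])
            amp = float(rng.uniform(amp_lo, amp_hi))
            phase = float(rng.uniform(0, 2 * np.pi))
            burst = gen_spindle(freq, amp, d, rate, phase)
            i0 = int(round(onset * rate))
            sig[i0 : i0 + burst.size] += burst
            placed.append((onset, onset + d))
            truth.append(
                SpindleEvent(
                    channel=ch, onset_s=onset, offset_s=onset + d,
                    amplitude_pp_uV=amp, mean_freq_hz=freq,
                    source="truth", label="true",
                )
            )
        samples[ci] = sig

    recording = Recording(
        subject_id=subject_id,
        channel_labels=params.channels,
        sampling_rate=rate,
        samples=samples,
    )
    truth_set = validate_set(truth)
    hyp = _cyclic_hypnogram(params.duration_min)
    try:
        fc = first_cycle(hyp)
        fc_min = round(fc.duration_min, 1)
        fc_count = sum(
            1
            for e in truth_set.on_channel(params.channels[0])
            if fc.start_s <= e.onset_s < fc.end_s
        )
    except ValueError:  # recording shorter than one full cycle
        fc_min, fc_count = None, None
    record = sio.SubjectRecord(
        subject_id=subject_id, group=group, psqi=psqi,
        first_cycle_min=fc_min, first_cycle_spindles=fc_count,
    )
    return recording, truth_set, hyp, record


def gen_experts(
    truth: EventSet,
    expert_params: ExpertParams | None = None,
    seed: int = 0,
    duration_s: float | None = None,
    channels: tuple[str, ...] | None = None,
    n_experts: int = 3,
) -> list[EventSet]:
    """Simulate imperfect annotators from the truth set.

    Each expert keeps a truth event with a probability logistic in its
    amplitude (centred so the mean-amplitude event is kept with
    ``detection_prob``), jitters both boundaries, and adds Poisson false
    events labelled ``"false"`` in the returned sets.
    """
    p = expert_params or ExpertParams()
    channels = channels or truth.channels or ("C3",)
    if duration_s is None:
        duration_s = max((e.offset_s for e in truth), default=60.0)
    amps = [e.amplitude_pp_uV for e in truth if e.amplitude_pp_uV is not None]
    amp_ref = float(np.mean(amps)) if amps else 0.0
    p0 = min(max(p.detection_prob, 1e-9), 1 - 1e-9)
    logit0 = np.log(p0 / (1 - p0))

    experts = []
    for xi in range(n_experts):
        rng = np.random.default_rng([seed, 1000 + xi])
        events: list[SpindleEvent] = []
        for e in truth:
            if e.amplitude_pp_uV is None or p.amp_slope_per_uV == 0:
                keep_p = p0
            else:
                keep_p = 1.0 / (
                    1.0 + np.exp(-(logit0 + p.amp_slope_per_uV * (e.amplitude_pp_uV - amp_ref)))
                )
            if rng.random() >= keep_p:
                continue
            onset = e.onset_s + rng.normal(0, p.jitter_sd_s)
            offset = e.offset_s + rng.normal(0, p.jitter_sd_s)
            onset = max(0.0, onset)
            offset = max(onset + 0.5, offset)  # duration floored at 0.5 s
            offset = min(offset, duration_s)
            if offset - onset < 0.5:
                onset = max(0.0, offset - 0.5)
            events.append(
                SpindleEvent(
                    channel=e.channel, onset_s=onset, offset_s=offset,
                    source="expert", label="true",
                )
            )
        minutes = duration_s / 60.0
        for ch in channels:
            n_false = rng.poisson(p.false_rate_per_min * minutes)
            for _ in range(n_false):
                d = float(
                    np.clip(rng.normal(0.8, 0.2), 0.5, 1.5)
                )
                onset = rng.uniform(0.0, max(duration_s - d, 1e-3))
                events.append(
                    SpindleEvent(
                        channel=ch, onset_s=onset, offset_s=onset + d,
                        source="expert", label="false",
                    )
                )
        experts.append(validate_set(events))
    return experts


def gen_cohort(
    params: CohortParams | None = None, out_dir: str | Path = "cohort"
) -> list[dict]:
    """Render and write the full cohort to ``out_dir``.

    Per subject: ``<id>.edf``, ``<id>_truth_events.csv``,
    ``<id>_expert{1,2,3}_events.csv`` and ``<id>_hypnogram.csv``; plus a
    cohort-level ``subjects.csv`` and ``params.yaml``.  Deterministic per
    master seed.
    """
    params = params or CohortParams()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    records = []
    for sid, group, idx in _subject_plan(params):
        rec, truth, hyp, srec = gen_subject(
            params, group, params.master_seed, subject_id=sid, subject_index=idx
        )
        sio.write_recording(rec, out / f"{sid}.edf")
        sio.write_events(truth, out / f"{sid}_truth_events.csv", subject_id=sid)
        experts = gen_experts(
            truth, params.expert,
            seed=np.random.SeedSequence([params.master_seed, idx]).generate_state(1)[0],
            duration_s=rec.duration_s, channels=params.channels,
        )
        for xi, es in enumerate(experts, start=1):
            sio.write_events(es, out / f"{sid}_expert{xi}_events.csv", subject_id=sid)
        sio.write_hypnogram(hyp, out / f"{sid}_hypnogram.csv")
        records.append(srec)
        manifest.append(
            {"subject_id": sid, "group": group,
             "edf": str(out / f"{sid}.edf"),
             "truth": str(out / f"{sid}_truth_events.csv"),
             "n_truth": len(truth)}
        )
    sio.write_subjects(records, out / "subjects.csv")
    with open(out / "params.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(params), fh, sort_keys=True)
    return manifest
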