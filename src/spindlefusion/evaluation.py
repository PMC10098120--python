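"""Expert-consensus ground truth, event and bin matching, the five
metrics (as percentages), and per-subject variance tables."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import (
    EventSet,
    SpindleEvent,
    overlap_fraction,
    validate_set,
)
from .preprocess import ScoringWindow

__all__ = [
    "ConsensusTruth",
    "ConfusionCounts",
    "MetricsRow",
    "consensus",
    "match_events",
    "binwise_confusion",
    "metrics",
    "variance_table",
    "compare_detectors",
]

METRIC_NAMES = ("recall", "precision", "specificity", "accuracy", "f1")


@dataclass(frozen=True)
class ConsensusTruth:
    """Two-of-three expert consensus: merged true events plus the
    unsupported (non-spindle) events."""

    true_set: EventSet
    false_set: EventSet


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")


@dataclass(frozen=True)
class MetricsRow:
    """The five metrics on the percentage scale.

    ``flagged`` lists metrics whose denominator was zero (reported as 0).
    """

    recall: float
    precision: float
    specificity: float
    accuracy: float
    f1: float
    flagged: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def consensus(
    expert_sets: Sequence[EventSet], match_fraction: float = 0.2
) -> ConsensusTruth:
    """Merge exactly three expert event sets into consensus truth.

    Events from different experts match when their overlap fraction is at
    least ``match_fraction``; transitively connected groups supported by
    two or more experts yield one true event spanning the union of the
    group's intervals; unsupported events form the false set.
    """
    if len(expert_sets) != 3:
        raise ValueError(f"consensus requires exactly 3 expert sets, got {len(expert_sets)}")
    true_events: list[SpindleEvent] = []
    false_events: list[SpindleEvent] = []
    channels = sorted({ch for es in expert_sets for ch in es.channels})
    for ch in channels:
        evs: list[SpindleEvent] = []
        owner: list[int] = []
        for xi, es in enumerate(expert_sets):
            for e in es.on_channel(ch):
                evs.append(e)
                owner.append(xi)
        parent = list(range(len(evs)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        order = sorted(range(len(evs)), key=lambda i: evs[i].onset_s)
        active: list[int] = []
        for i in order:
            active = [j for j in active if evs[j].offset_s > evs[i].onset_s]
            for j in active:
                if owner[i] != owner[j] and overlap_fraction(evs[i], evs[j]) >= match_fraction:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
            active.append(i)
        groups: dict[int, list[int]] = {}
        for i in range(len(evs)):
            groups.setdefault(find(i), []).append(i)
        for members in groups.values():
            experts_in = {owner[i] for i in members}
            if len(experts_in) >= 2:
                onset = min(evs[i].onset_s for i in members)
                offset = max(evs[i].offset_s for i in members)
                true_events.append(
                    SpindleEvent(
                        channel=ch, onset_s=onset, offset_s=offset,
                        source="truth", label="true",
                    )
                )
            else:
                false_events.extend(
                    SpindleEvent(
                        channel=ch, onset_s=evs[i].onset_s, offset_s=evs[i].offset_s,
                        source="expert", label="false",
                    )
                    for i in members
                )
    return ConsensusTruth(validate_set(true_events), validate_set(false_events))


def match_events(
    pred: EventSet, truth_true: EventSet, match_fraction: float = 0.2
) -> tuple[int, int, int]:
    """Greedy one-to-one event matching in onset order -> (tp, fp, fn)."""
    tp = 0
    matched: set[int] = set()
    for ch in sorted(set(pred.channels) | set(truth_true.channels)):
        p_events = pred.on_channel(ch)
        t_events = truth_true.on_channel(ch)
        used = [False] * len(t_events)
        for p in p_events:
            for ti, t in enumerate(t_events):
                if used[ti]:
                    continue
                if t.onset_s >= p.offset_s:
                    break
                if overlap_fraction(p, t) >= match_fraction:
                    used[ti] = True
                    tp += 1
                    break
    fp = len(pred) - tp
    fn = len(truth_true) - tp
    return tp, fp, fn


def _bin_positive(
    events: Sequence[SpindleEvent], edges: np.ndarray, bin_s: float
) -> np.ndarray:
    """Bin is positive when >= 50% of it is covered by the event union."""
    cover = np.zeros(edges.size - 1)
    for e in events:
        lo = np.clip(e.onset_s, edges[0], edges[-1])
        hi = np.clip(e.offset_s, edges[0], edges[-1])
        first = int(np.floor((lo - edges[0]) / bin_s))
        last = int(np.ceil((hi - edges[0]) / bin_s))
        for b in range(first, min(last, cover.size)):
            seg = min(hi, edges[b + 1]) - max(lo, edges[b])
            if seg > 0:
                cover[b] += seg
    return cover >= 0.5 * bin_s


def binwise_confusion(
    pred: EventSet,
    truth_true: EventSet,
    window: ScoringWindow,
    bin_s: float = 0.5,
) -> ConfusionCounts:
    """Discretize the window into ``bin_s`` bins and count the confusion
    between predicted and true bin coverage."""
    for e in list(pred) + list(truth_true):
        if e.onset_s < window.start_s - 1e-9 or e.offset_s > window.end_s + 1e-9:
            raise ValueError(
                f"event [{e.onset_s}, {e.offset_s}) outside scoring window "
                f"[{window.start_s}, {window.end_s})"
            )
    n_bins = int(round(window.duration_s / bin_s))
    edges = window.start_s + np.arange(n_bins + 1) * bin_s
    p = _bin_positive(list(pred), edges, bin_s)
    t = _bin_positive(list(truth_true), edges, bin_s)
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
    )


def label_predictions(
    pred: EventSet, truth_true: EventSet, match_fraction: float = 0.2
) -> dict[SpindleEvent, str]:
    """Label each candidate event against the truth: ``"true"`` when it
    overlaps any true event by at least ``match_fraction``, else
    ``"false"``.  Feeds cluster rejection (many-to-one is fine here)."""
    labels: dict[SpindleEvent, str] = {}
    for ch in pred.channels:
        t_events = truth_true.on_channel(ch)
        for p in pred.on_channel(ch):
            hit = any(
                t.onset_s < p.offset_s
                and p.onset_s < t.offset_s
                and overlap_fraction(p, t) >= match_fraction
                for t in t_events
            )
            labels[p] = "true" if hit else "false"
    return labels


def metrics(c: ConfusionCounts) -> MetricsRow:
    """Recall, precision, specificity, accuracy, F1 as percentages.

    Metrics with a zero denominator are reported as 0 and flagged.
    """
    total = c.tp + c.fp + c.fn + c.tn
    if total == 0:
        raise ValueError("metrics undefined: all confusion counts are zero")
    flagged = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            flagged.append(name)
            return 0.0
        return 100.0 * num / den

    recall = ratio(c.tp, c.tp + c.fn, "recall")
    precision = ratio(c.tp, c.tp + c.fp, "precision")
    specificity = ratio(c.tn, c.tn + c.fp, "specificity")
    accuracy = 100.0 * (c.tp + c.tn) / total
    if precision + recall == 0:
        f1 = 0.0
        flagged.append("f1")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsRow(
        recall=recall,
        precision=precision,
        specificity=specificity,
        accuracy=accuracy,
        f1=f1,
        flagged=tuple(flagged),
    )


def variance_table(per_subject: Sequence[MetricsRow]) -> dict[str, float]:
    """Sample variance (n-1) of each metric over subjects, percentage scale."""
    if len(per_subject) < 2:
        raise ValueError("variance_table needs at least 2 subjects")
    return {
        name: float(np.var([getattr(row, name) for row in per_subject], ddof=1))
        for name in METRIC_NAMES
    }


def evaluate_subject(
    pred: EventSet,
    truth_true: EventSet,
    window: ScoringWindow,
    match_fraction: float = 0.2,
    bin_s: float = 0.5,
) -> MetricsRow:
    """Event-level recall/precision/F1 with bin-level specificity/accuracy."""
    tp, fp, fn = match_events(pred, truth_true, match_fraction)
    event_row = metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=0))
    bin_row = metrics(binwise_confusion(pred, truth_true, window, bin_s))
    return MetricsRow(
        recall=event_row.recall,
        precision=event_row.precision,
        specificity=bin_row.specificity,
        accuracy=bin_row.accuracy,
        f1=event_row.f1,
        flagged=tuple(set(event_row.flagged) - {"specificity", "accuracy"}),
    )


def compare_detectors(
    cohort: Sequence[Mapping],
    config=None,
) -> dict[str, dict]:
    """Run wavelet-only, RMS-only and fusion per subject; summarize each
    metric's max/min/mean and variance per method.

    Each cohort entry is a mapping with keys ``recording``, ``truth``
    (EventSet), ``window`` (ScoringWindow) and optionally ``labels``.
    """
    from .detectors import detect_rms, detect_wavelet
    from .fusion import fuse
    from .io import RunConfig

    if not cohort:
        raise ValueError("compare_detectors: empty cohort")
    config = config or RunConfig()
    per_method: dict[str, list[MetricsRow]] = {"wavelet": [], "rms": [], "fusion": []}
    for entry in cohort:
        rec = entry["recording"]
        truth = entry["truth"]
        window = entry["window"]
        labels = entry.get("labels")
        sets = {}
        for ch in rec.channel_labels:
            sig = rec.segment(ch, window.start_s, window.end_s)
            sets.setdefault("wavelet", []).extend(
                detect_wavelet(sig, rec.sampling_rate, config, channel=ch, t0_s=window.start_s)
            )
            sets.setdefault("rms", []).extend(
                detect_rms(sig, rec.sampling_rate, config, channel=ch, t0_s=window.start_s)
            )
        wl = validate_set(sets["wavelet"])
        rm = validate_set(sets["rms"])
        mf, bs = config.evaluation.match_fraction, config.evaluation.bin_s
        if labels is None:
            labels = label_predictions(
                validate_set(list(wl) + list(rm)), truth, mf
            )
        fu = fuse(rec, wl, rm, labels=labels, config=config)
        per_method["wavelet"].append(evaluate_subject(wl, truth, window, mf, bs))
        per_method["rms"].append(evaluate_subject(rm, truth, window, mf, bs))
        per_method["fusion"].append(evaluate_subject(fu, truth, window, mf, bs))

    report: dict[str, dict] = {}
    for method, rows in per_method.items():
        summary: dict[str, dict[str, float]] = {}
        for name in METRIC_NAMES:
            vals = [getattr(r, name) for r in rows]
            summary[name] = {
                "max": float(np.max(vals)),
                "min": float(np.min(vals)),
                "mean": float(np.mean(vals)),
            }
        if len(rows) >= 2:
            var = variance_table(rows)
            for name in METRIC_NAMES:
                summary[name]["variance"] = var[name]
        else:
            warnings.warn("single-subject cohort: variance omitted", stacklevel=2)
        report[method] = {"per_subject": rows, "summary": summary}
    return report
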