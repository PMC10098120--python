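"""Detector fusion: overlap partitioning, duration-based overlap
resolution, k-means++ clustering of unique detections on (amplitude,
frequency), and label-driven cluster rejection.

Pipeline: partition the two detectors' outputs into transitively
overlapping groups and unique events; each mixed group contributes its
longest member to the overlap set; unique events are clustered in
standardized (amplitude, frequency) space and clusters dominated by
labelled non-spindles are dropped; the survivors are unioned with the
overlap set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from . import features as feat
from .io import RunConfig
from .model import EventSet, Recording, SpindleEvent, duration, overlaps, validate_set

__all__ = [
    "FeatureVector",
    "ClusterModel",
    "partition",
    "resolve_overlap",
    "event_features",
    "kmeans_improved",
    "reject_clusters",
    "fuse",
]

log = logging.getLogger(__name__)

_SOURCE_ORDER = {"wavelet": 0, "rms": 1, "fusion": 2, "expert": 3, "truth": 4}


@dataclass(frozen=True)
class FeatureVector:
    event: SpindleEvent
    amplitude_pp_uV: float
    mean_freq_hz: float
    z_amplitude: float
    z_frequency: float


@dataclass(frozen=True)
class ClusterModel:
    k: int
    centroids: np.ndarray
    assignment: tuple[int, ...]
    vectors: tuple[FeatureVector, ...]
    seed: int
    n_iter: int


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def resolve_overlap(group: Sequence[SpindleEvent]) -> SpindleEvent:
    """Representative of an overlap group: longest duration, ties broken
    by earlier onset, then wavelet before rms."""
    if len(group) < 2:
        raise ValueError("resolve_overlap needs a group of >= 2 events")
    return min(
        group,
        key=lambda e: (-duration(e), e.onset_s, _SOURCE_ORDER.get(e.source, 9)),
    )


def partition(set_a: EventSet, set_b: EventSet) -> tuple[EventSet, EventSet]:
    """Split two detectors' events into overlap representatives and uniques.

    Transitively overlapping events form one group; a group containing
    both detectors contributes a single representative (longest member)
    to the overlap set; all other events are unique.
    """
    overlap_events: list[SpindleEvent] = []
    unique_events: list[SpindleEvent] = []
    channels = sorted(set(set_a.channels) | set(set_b.channels))
    for ch in channels:
        evs = list(set_a.on_channel(ch)) + list(set_b.on_channel(ch))
        srcs = ["A"] * len(set_a.on_channel(ch)) + ["B"] * len(set_b.on_channel(ch))
        order = sorted(range(len(evs)), key=lambda i: evs[i].onset_s)
        uf = _UnionFind(len(evs))
        # sweep: overlapping intervals are adjacent in onset order
        active: list[int] = []
        for i in order:
            active = [j for j in active if evs[j].offset_s > evs[i].onset_s]
            for j in active:
                if overlaps(evs[i], evs[j]):
                    uf.union(i, j)
            active.append(i)
        groups: dict[int, list[int]] = {}
        for i in range(len(evs)):
            groups.setdefault(uf.find(i), []).append(i)
        for members in groups.values():
            member_srcs = {srcs[i] for i in members}
            if len(members) >= 2 and member_srcs == {"A", "B"}:
                overlap_events.append(resolve_overlap([evs[i] for i in members]))
            else:
                unique_events.extend(evs[i] for i in members)
    return validate_set(overlap_events), validate_set(unique_events)


def event_features(
    recording: Recording, events: EventSet | Sequence[SpindleEvent]
) -> list[FeatureVector]:
    """(amplitude, frequency) per event, z-scored over the input population.

    Standardization uses the sample SD (n-1); a zero-SD dimension (or a
    single-event population) maps to z = 0.
    """
    evs = list(events)
    if not evs:
        return []
    amps = np.array([feat.amplitude_pp(recording, e) for e in evs])
    frqs = np.array([feat.mean_frequency(recording, e) for e in evs])

    def zscore(x: np.ndarray) -> np.ndarray:
        if x.size < 2:
            return np.zeros_like(x)
        sd = x.std(ddof=1)
        if sd == 0:
            return np.zeros_like(x)
        return (x - x.mean()) / sd

    za, zf = zscore(amps), zscore(frqs)
    return [
        FeatureVector(
            event=e,
            amplitude_pp_uV=float(amps[i]),
            mean_freq_hz=float(frqs[i]),
            z_amplitude=float(za[i]),
            z_frequency=float(zf[i]),
        )
        for i, e in enumerate(evs)
    ]


def kmeans_improved(
    vectors: Sequence[FeatureVector],
    k_range: Sequence[int] = range(2, 7),
    seed: int = 0,
) -> ClusterModel:
    """k-means++ with silhouette-selected k; deterministic given the seed.

    Falls back to a single cluster when the vectors do not support k >= 2
    (fewer than 2 distinct points).
    """
    if not vectors:
        raise ValueError("kmeans_improved: empty input")
    X = np.array([[v.z_amplitude, v.z_frequency] for v in vectors])
    n_distinct = np.unique(X, axis=0).shape[0]
    candidates = [k for k in k_range if 2 <= k <= len(vectors) - 1 and k <= n_distinct]
    if not candidates:
        return ClusterModel(
            k=1,
            centroids=X.mean(axis=0, keepdims=True),
            assignment=tuple(0 for _ in vectors),
            vectors=tuple(vectors),
            seed=seed,
            n_iter=0,
        )
    best = None
    for k in candidates:
        km = KMeans(
            n_clusters=k, init="k-means++", n_init=10, max_iter=300, tol=1e-6,
            random_state=seed,
        ).fit(X)
        score = silhouette_score(X, km.labels_) if len(set(km.labels_)) > 1 else -1.0
        if best is None or score > best[0]:
            best = (score, k, km)
    _, k, km = best
    return ClusterModel(
        k=k,
        centroids=km.cluster_centers_.copy(),
        assignment=tuple(int(l) for l in km.labels_),
        vectors=tuple(vectors),
        seed=seed,
        n_iter=int(km.n_iter_),
    )


def reject_clusters(
    model: ClusterModel,
    labels: Mapping[SpindleEvent, str] | None = None,
    reject_fraction: float = 0.5,
) -> EventSet:
    """Drop clusters whose labelled members are mostly non-spindles.

    A cluster is discarded iff, among its labelled members, the
    proportion labelled ``"false"`` strictly exceeds ``reject_fraction``.
    Clusters with no labelled member are kept.
    """
    labels = labels or {}
    counts: dict[int, list[int]] = {c: [0, 0] for c in range(model.k)}  # [false, labeled]
    for vec, cluster in zip(model.vectors, model.assignment):
        lab = labels.get(vec.event, vec.event.label)
        if lab in ("true", "false"):
            counts[cluster][1] += 1
            if lab == "false":
                counts[cluster][0] += 1
    kept_clusters = {
        c
        for c, (n_false, n_labeled) in counts.items()
        if n_labeled == 0 or n_false / n_labeled <= reject_fraction
    }
    return validate_set(
        vec.event
        for vec, cluster in zip(model.vectors, model.assignment)
        if cluster in kept_clusters
    )


def fuse(
    recording: Recording,
    set_a: EventSet,
    set_b: EventSet,
    labels: Mapping[SpindleEvent, str] | None = None,
    config: RunConfig | None = None,
) -> EventSet:
    """Full fusion: partition, resolve overlaps, cluster + reject uniques,
    union, and re-tag sources as ``fusion``."""
    config = config or RunConfig()
    overlap_set, unique_set = partition(set_a, set_b)
    if not unique_set:
        kept_unique: Sequence[SpindleEvent] = ()
    elif not labels and all(e.label == "unknown" for e in unique_set):
        log.warning(
            "fuse: no labels available; cluster rejection skipped, all unique "
            "detections kept"
        )
        kept_unique = tuple(unique_set)
    else:
        vectors = event_features(recording, unique_set)
        model = kmeans_improved(
            vectors,
            range(config.fusion.k_min, config.fusion.k_max + 1),
            seed=config.fusion.seed,
        )
        kept_unique = tuple(
            reject_clusters(model, labels, config.fusion.reject_fraction)
        )
    final = [replace(e, source="fusion") for e in list(overlap_set) + list(kept_unique)]
    return validate_set(final)
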