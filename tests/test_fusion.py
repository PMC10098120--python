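import numpy as np
import pytest

from spindlefusion.fusion import (
    FeatureVector,
    event_features,
    fuse,
    kmeans_improved,
    partition,
    reject_clusters,
    resolve_overlap,
)
from spindlefusion.io import RunConfig
from spindlefusion.model import SpindleEvent, validate_set

from conftest import make_recording


def ev(onset, offset, source="wavelet", channel="C3", **kw):
    return SpindleEvent(channel=channel, onset_s=onset, offset_s=offset, source=source, **kw)


def vec(x, y, onset=0.0):
    e = ev(onset, onset + 1.0)
    return FeatureVector(
        event=e, amplitude_pp_uV=1.0, mean_freq_hz=13.0, z_amplitude=x, z_frequency=y
    )


class TestResolveOverlap:
    def test_longer_wins(self):
        a = ev(10.0, 10.8, "wavelet")
        b = ev(10.5, 11.6, "rms")
        assert resolve_overlap([a, b]) == b

    def test_tie_earlier_onset(self):
        a = ev(10.0, 11.0, "rms")
        b = ev(10.2, 11.2, "wavelet")
        assert resolve_overlap([a, b]) == a

    def test_tie_detector_order(self):
        a = ev(10.0, 11.0, "rms")
        b = ev(10.0, 11.0, "wavelet")
        assert resolve_overlap([a, b]) == b  # wavelet before rms

    def test_three_chain(self):
        evs = [ev(0.0, 0.6), ev(0.5, 1.4, "rms"), ev(1.3, 2.0)]
        assert resolve_overlap(evs) == evs[1]

    def test_singleton_fault(self):
        with pytest.raises(ValueError):
            resolve_overlap([ev(0, 1)])


class TestPartition:
    def test_overlapping_pair(self):
        a = validate_set([ev(10.0, 10.8, "wavelet")])
        b = validate_set([ev(10.5, 11.6, "rms")])
        overlap, unique = partition(a, b)
        assert len(overlap) == 1 and len(unique) == 0
        rep = list(overlap)[0]
        assert (rep.onset_s, rep.offset_s) == (10.5, 11.6)

    def test_disjoint(self):
        a = validate_set([ev(10, 11, "wavelet")])
        b = validate_set([ev(20, 21, "rms")])
        overlap, unique = partition(a, b)
        assert len(overlap) == 0 and len(unique) == 2

    def test_empty_a(self):
        b = validate_set([ev(i * 10.0, i * 10.0 + 1, "rms") for i in range(5)])
        overlap, unique = partition(validate_set([]), b)
        assert len(overlap) == 0 and len(unique) == 5

    def test_covers_every_event_once(self):
        a = validate_set([ev(0, 1, "wavelet"), ev(5, 6, "wavelet")])
        b = validate_set([ev(0.5, 1.5, "rms"), ev(10, 11, "rms")])
        overlap, unique = partition(a, b)
        assert len(overlap) + len(unique) == 3  # one group collapsed

    def test_same_detector_overlap_stays_unique(self):
        # two wavelet events overlapping each other but nothing from rms
        a = validate_set([ev(0.0, 1.0, "wavelet"), ev(0.5, 1.5, "wavelet")])
        overlap, unique = partition(a, validate_set([]))
        assert len(overlap) == 0 and len(unique) == 2


class TestEventFeatures:
    def test_single_event_degenerate_z(self, sine_recording):
        vecs = event_features(sine_recording, [ev(2.0, 3.0)])
        assert vecs[0].z_amplitude == 0.0 and vecs[0].z_frequency == 0.0

    def test_two_event_sample_sd(self):
        # amplitudes 20 and 40 uV at equal frequency -> z = +-1/sqrt(2)
        rate = 256.0
        t = np.arange(int(10 * rate)) / rate
        sig = np.zeros_like(t)
        for onset, amp in [(1.0, 10.0), (5.0, 20.0)]:
            seg = (t >= onset) & (t < onset + 1.0)
            sig[seg] = amp * np.sin(2 * np.pi * 13.0 * t[seg])
        rec = make_recording(sig, rate)
        vecs = event_features(rec, [ev(1.0, 2.0), ev(5.0, 6.0)])
        assert vecs[0].z_amplitude == pytest.approx(-np.sqrt(0.5), abs=0.01)
        assert vecs[1].z_amplitude == pytest.approx(+np.sqrt(0.5), abs=0.01)
        # raw frequencies agree (n=2 z-scores degenerate to +-1/sqrt(2)
        # for any nonzero numerical difference, so compare pre-standardized)
        assert vecs[0].mean_freq_hz == pytest.approx(vecs[1].mean_freq_hz, abs=0.1)

    def test_programmed_frequency_recovered(self, small_subject):
        rec, truth, _, _ = small_subject
        sample = list(truth)[:10]
        vecs = event_features(rec, sample)
        for v, e in zip(vecs, sample):
            assert v.mean_freq_hz == pytest.approx(e.mean_freq_hz, abs=0.35)

    def test_event_outside_recording(self, sine_recording):
        with pytest.raises(ValueError):
            event_features(sine_recording, [ev(100.0, 101.0)])


class TestKmeansImproved:
    def test_two_blobs(self):
        rng = np.random.default_rng(7)
        pts = np.vstack(
            [rng.normal((-2, -2), 0.3, (100, 2)), rng.normal((2, 2), 0.3, (100, 2))]
        )
        vecs = [vec(x, y, onset=i * 2.0) for i, (x, y) in enumerate(pts)]
        model = kmeans_improved(vecs, seed=7)
        assert model.k == 2
        labels = np.asarray(model.assignment)
        blob = np.array([0] * 100 + [1] * 100)
        agree = max(np.mean(labels == blob), np.mean(labels != blob))
        assert agree >= 0.99

    def test_identical_points(self):
        vecs = [vec(1.0, 1.0, onset=i * 2.0) for i in range(10)]
        model = kmeans_improved(vecs, seed=0)
        assert model.k == 1
        assert np.allclose(model.centroids, [[1.0, 1.0]])

    def test_determinism(self):
        rng = np.random.default_rng(3)
        vecs = [vec(x, y, onset=i * 2.0) for i, (x, y) in enumerate(rng.normal(size=(40, 2)))]
        m1 = kmeans_improved(vecs, seed=5)
        m2 = kmeans_improved(vecs, seed=5)
        assert m1.k == m2.k
        assert m1.assignment == m2.assignment
        assert np.allclose(m1.centroids, m2.centroids)

    def test_empty_input(self):
        with pytest.raises(ValueError):
            kmeans_improved([])


class TestRejectClusters:
    def _model(self, assignment, events):
        vecs = tuple(
            FeatureVector(e, 1.0, 13.0, 0.0, 0.0) for e in events
        )
        return __import__("spindlefusion.fusion", fromlist=["ClusterModel"]).ClusterModel(
            k=max(assignment) + 1,
            centroids=np.zeros((max(assignment) + 1, 2)),
            assignment=tuple(assignment),
            vectors=vecs,
            seed=0,
            n_iter=1,
        )

    def test_mostly_false_discarded(self):
        events = [ev(i * 2.0, i * 2.0 + 1, label="false" if i < 8 else "true") for i in range(10)]
        model = self._model([0] * 10, events)
        assert len(reject_clusters(model)) == 0

    def test_exactly_half_kept(self):
        events = [ev(i * 2.0, i * 2.0 + 1, label="false" if i < 5 else "true") for i in range(10)]
        model = self._model([0] * 10, events)
        assert len(reject_clusters(model)) == 10  # strict inequality

    def test_unlabeled_cluster_kept(self):
        events = [ev(i * 2.0, i * 2.0 + 1) for i in range(4)]
        model = self._model([0] * 4, events)
        assert len(reject_clusters(model)) == 4

    def test_label_map_overrides(self):
        events = [ev(i * 2.0, i * 2.0 + 1) for i in range(4)]
        model = self._model([0] * 4, events)
        labels = {e: "false" for e in events}
        assert len(reject_clusters(model, labels)) == 0


class TestFuse:
    def test_identical_detectors(self, sine_recording):
        evs = [ev(1.0, 2.0, "wavelet"), ev(4.0, 5.0, "wavelet")]
        a = validate_set(evs)
        b = validate_set([ev(1.0, 2.0, "rms"), ev(4.0, 5.0, "rms")])
        out = fuse(sine_recording, a, b)
        assert len(out) == 2
        assert all(e.source == "fusion" for e in out)

    def test_unique_empty_returns_overlap(self, sine_recording):
        a = validate_set([ev(1.0, 2.0, "wavelet")])
        b = validate_set([ev(1.2, 2.2, "rms")])
        out = fuse(sine_recording, a, b)
        assert len(out) == 1

    def test_no_labels_keeps_everything(self, sine_recording):
        a = validate_set([ev(1.0, 2.0, "wavelet")])
        b = validate_set([ev(5.0, 6.0, "rms")])
        out = fuse(sine_recording, a, b, labels=None)
        assert len(out) == 2  # nothing rejectable without labels

    def test_never_invents_events(self, small_subject, default_config):
        from spindlefusion.detectors import detect_rms, detect_wavelet

        rec, truth, _, _ = small_subject
        wl = detect_wavelet(rec.channel("C3"), rec.sampling_rate, default_config)
        rm = detect_rms(rec.channel("C3"), rec.sampling_rate, default_config)
        out = fuse(rec, wl, rm, config=default_config)
        inputs = {(e.onset_s, e.offset_s) for e in list(wl) + list(rm)}
        for e in out:
            assert (e.onset_s, e.offset_s) in inputs

    def test_determinism(self, small_subject, default_config):
        from spindlefusion.detectors import detect_rms, detect_wavelet
        from spindlefusion.evaluation import label_predictions

        rec, truth, _, _ = small_subject
        wl = detect_wavelet(rec.channel("C3"), rec.sampling_rate, default_config)
        rm = detect_rms(rec.channel("C3"), rec.sampling_rate, default_config)
        labels = label_predictions(validate_set(list(wl) + list(rm)), truth)
        out1 = fuse(rec, wl, rm, labels=labels, config=default_config)
        out2 = fuse(rec, wl, rm, labels=labels, config=default_config)
        assert out1 == out2
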