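import numpy as np
import pytest
from scipy import signal as sps
from scipy import stats as sstats

from spindlefusion.evaluation import consensus, match_events
from spindlefusion.features import mean_frequency
from spindlefusion.model import Recording, overlaps
from spindlefusion.synth import (
    CohortParams,
    ExpertParams,
    _draw_duration,
    _draw_frequency,
    draw_cohort_traits,
    gen_background,
    gen_cohort,
    gen_experts,
    gen_spindle,
    gen_subject,
)

RATE = 256.0


class TestBackground:
    def test_rms_within_tolerance(self):
        sig = gen_background(60.0, RATE, rms_uV=15.0, seed=0)
        rms = np.sqrt(np.mean(sig**2))
        assert 14.85 <= rms <= 15.15

    def test_determinism(self):
        a = gen_background(10.0, RATE, seed=5)
        b = gen_background(10.0, RATE, seed=5)
        assert np.array_equal(a, b)

    def test_alpha_zero_flat_spectrum(self):
        sig = gen_background(600.0, RATE, rms_uV=10.0, alpha=0.0, seed=1)
        f, pxx = sps.welch(sig, fs=RATE, nperseg=4096)
        low = pxx[(f >= 1) & (f <= 10)].mean()
        high = pxx[(f >= 40) & (f <= 49)].mean()
        assert abs(low - high) / max(low, high) < 0.2

    def test_alpha_one_pink_slope(self):
        sig = gen_background(600.0, RATE, rms_uV=10.0, alpha=1.0, seed=1)
        f, pxx = sps.welch(sig, fs=RATE, nperseg=4096)
        low = pxx[(f >= 1) & (f <= 2)].mean()
        high = pxx[(f >= 32) & (f <= 64)].mean()
        assert low > 10 * high

    def test_bad_args(self):
        with pytest.raises(ValueError):
            gen_background(-1.0, RATE)


class TestSpindleWaveform:
    def test_peak_to_peak(self):
        w = gen_spindle(13.0, 40.0, 1.0, RATE)
        assert 38.0 <= w.max() - w.min() <= 42.0

    def test_mean_frequency_cross_module(self):
        w = gen_spindle(13.0, 40.0, 1.0, RATE)
        pad = np.zeros(int(2 * RATE))
        rec = Recording("t", ("C3",), RATE, np.concatenate([pad, w, pad])[None, :])
        from spindlefusion.model import SpindleEvent

        e = SpindleEvent(channel="C3", onset_s=2.0, offset_s=3.0)
        assert mean_frequency(rec, e) == pytest.approx(13.0, abs=0.25)

    def test_duration_out_of_range(self):
        with pytest.raises(ValueError):
            gen_spindle(13.0, 40.0, 0.4, RATE)

    def test_frequency_out_of_range(self):
        with pytest.raises(ValueError):
            gen_spindle(10.0, 40.0, 1.0, RATE)


class TestMarginals:
    def test_duration_ks(self):
        params = CohortParams()
        rng = np.random.default_rng(0)
        x = _draw_duration(rng, params, 1000)
        lo, hi = params.duration_bounds_s
        a = (lo - params.duration_mean_s) / params.duration_sd_s
        b = (hi - params.duration_mean_s) / params.duration_sd_s
        d, p = sstats.kstest(
            x, sstats.truncnorm(a, b, loc=params.duration_mean_s,
                                scale=params.duration_sd_s).cdf
        )
        assert p > 0.01

    def test_frequency_ks(self):
        params = CohortParams()
        rng = np.random.default_rng(1)
        x = _draw_frequency(rng, params, 1000)

        def cdf(v):
            v = np.asarray(v, dtype=float)
            out = np.zeros_like(v)
            m = 0.3  # side mass; split 1/3 to [11,12), 2/3 to (14,16]
            out = np.where(v < 11, 0.0, out)
            seg1 = (v >= 11) & (v < 12)
            out = np.where(seg1, m / 3 * (v - 11), out)
            seg2 = (v >= 12) & (v < 14)
            out = np.where(seg2, m / 3 + 0.7 * (v - 12) / 2, out)
            seg3 = (v >= 14) & (v <= 16)
            out = np.where(seg3, m / 3 + 0.7 + 2 * m / 3 * (v - 14) / 2, out)
            return np.where(v > 16, 1.0, out)

        d, p = sstats.kstest(x, cdf)
        assert p > 0.01
        assert np.mean((x >= 12) & (x <= 14)) == pytest.approx(0.7, abs=0.05)

    def test_amplitude_uniform_ks(self):
        params = CohortParams()
        rng = np.random.default_rng(2)
        lo, hi = params.amplitude_range("NS")
        x = rng.uniform(lo, hi, 1000)
        d, p = sstats.kstest(x, sstats.uniform(lo, hi - lo).cdf)
        assert p > 0.01


class TestGenSubject:
    def test_truth_count_poisson_bound(self):
        params = CohortParams(
            channels=("C3",), duration_min=60.0,
            density_range_ns=(2.0, 2.0),  # pin density at 2/min
        )
        _, truth, _, _ = gen_subject(params, "NS", seed=3)
        assert 76 <= len(truth) <= 164  # Poisson mean 120 +- 4 sigma

    def test_truth_durations_and_nonoverlap(self, small_subject):
        _, truth, _, _ = small_subject
        evs = list(truth)
        for e in evs:
            assert 0.5 <= e.duration_s <= 1.5
        for a, b in zip(evs, evs[1:]):
            assert not overlaps(a, b)

    def test_determinism(self, small_params):
        a = gen_subject(small_params, "DS", seed=9)
        b = gen_subject(small_params, "DS", seed=9)
        assert np.array_equal(a[0].samples, b[0].samples)
        assert a[1] == b[1]
        assert a[3] == b[3]

    def test_psqi_clipped_to_group(self, small_params):
        for seed in range(5):
            _, _, _, rec_ds = gen_subject(small_params, "DS", seed=seed)
            _, _, _, rec_ns = gen_subject(small_params, "NS", seed=seed)
            assert 11 <= rec_ds.psqi <= 21
            assert 0 <= rec_ns.psqi <= 10


class TestGenExperts:
    def _flat_truth(self, n=200, amp=40.0):
        from spindlefusion.model import SpindleEvent, validate_set

        return validate_set(
            SpindleEvent(
                channel="C3", onset_s=i * 3.0, offset_s=i * 3.0 + 1.0,
                amplitude_pp_uV=amp, mean_freq_hz=13.0,
                source="truth", label="true",
            )
            for i in range(n)
        )

    def test_perfect_experts_reproduce_truth(self):
        truth = self._flat_truth(30)
        perfect = ExpertParams(
            detection_prob=1.0, amp_slope_per_uV=0.0,
            jitter_sd_s=0.0, false_rate_per_min=0.0,
        )
        experts = gen_experts(truth, perfect, seed=0, duration_s=100.0)
        for es in experts:
            assert len(es) == 30
            assert match_events(es, truth) == (30, 0, 0)
        ct = consensus(experts)
        assert len(ct.true_set) == 30
        assert len(ct.false_set) == 0

    def test_blind_experts_empty(self):
        truth = self._flat_truth(20)
        blind = ExpertParams(detection_prob=0.0, false_rate_per_min=0.0)
        experts = gen_experts(truth, blind, seed=0, duration_s=100.0)
        assert all(len(es) == 0 for es in experts)
        ct = consensus([es for es in experts])
        assert len(ct.true_set) == 0

    def test_default_consensus_recall(self):
        # two-of-three with p = 0.9: expected recall ~ 0.972
        truth = self._flat_truth(200)
        experts = gen_experts(truth, ExpertParams(), seed=4, duration_s=700.0)
        ct = consensus(experts)
        tp, fp, fn = match_events(ct.true_set, truth)
        assert tp / (tp + fn) >= 0.95

    def test_expert_durations_floored(self):
        truth = self._flat_truth(50)
        experts = gen_experts(truth, ExpertParams(jitter_sd_s=0.3), seed=1, duration_s=200.0)
        for es in experts:
            for e in es:
                assert e.duration_s >= 0.5 - 1e-9


class TestTraits:
    def test_group_density_separation(self):
        traits = draw_cohort_traits(CohortParams(master_seed=42))
        ds = [d for _, g, d, _ in traits if g == "DS"]
        ns = [d for _, g, d, _ in traits if g == "NS"]
        assert len(ds) == 20 and len(ns) == 10
        assert np.mean(ds) < np.mean(ns)

    def test_null_coupling_centered_at_zero(self):
        from spindlefusion.stats import pearson

        null = CohortParams(
            psqi_b=0.0, psqi_a=10.0,
            density_range_ds=(1.0, 3.0), density_range_ns=(1.0, 3.0),
            psqi_clip_ds=(0, 21), psqi_clip_ns=(0, 21),
        )
        rs = []
        for seed in range(100):
            traits = draw_cohort_traits(null, seed=seed)
            rs.append(pearson([t[3] for t in traits], [t[2] for t in traits]).r)
        assert abs(np.mean(rs)) < 0.15

    def test_matches_rendered_subject(self):
        # the fast trait path uses the same substreams as gen_subject
        params = CohortParams(n_ds=1, n_ns=0, channels=("C3",), duration_min=2.0,
                              master_seed=13)
        sid, group, density, psqi = draw_cohort_traits(params)[0]
        _, _, _, srec = gen_subject(params, group, seed=13, subject_id=sid,
                                    subject_index=0)
        assert srec.psqi == int(psqi)


class TestGenCohort:
    def test_tiny_cohort_on_disk(self, tmp_path):
        params = CohortParams(
            n_ds=1, n_ns=1, duration_min=2.0, channels=("C3", "C4"), master_seed=7
        )
        manifest = gen_cohort(params, tmp_path)
        assert len(manifest) == 2
        assert {m["group"] for m in manifest} == {"DS", "NS"}
        for sid in ("DS1", "NS1"):
            assert (tmp_path / f"{sid}.edf").exists()
            assert (tmp_path / f"{sid}_truth_events.csv").exists()
            for xi in (1, 2, 3):
                assert (tmp_path / f"{sid}_expert{xi}_events.csv").exists()
            assert (tmp_path / f"{sid}_hypnogram.csv").exists()
        assert (tmp_path / "subjects.csv").exists()
        assert (tmp_path / "params.yaml").exists()
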