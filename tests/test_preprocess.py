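import numpy as np
import pytest

from lognecg.model import GRID, synthesize_vector
from lognecg.preprocess import (
    BeatEpoch,
    EcgSegment,
    SegmentRejected,
    UndefinedSnrError,
    detect_r_peaks,
    epoch_beats,
    filter_segments,
    resample_to_1024,
    segment_quality,
    snr_db,
)
from lognecg.synth import SynthSpec, render_trace


@pytest.fixture(scope="module")
def clean_trace(proto_vec):
    spec = SynthSpec(target_snr_db=None, mean_rr_s=0.5, rr_jitter_s=0.01)
    rng = np.random.default_rng(42)
    vecs = np.tile(proto_vec, (130, 1))
    seg, r_times = render_trace(vecs, spec, rng)
    return seg, r_times


class TestResample:
    def test_identity_at_1024(self):
        seg = EcgSegment(samples=np.sin(np.arange(2048) / 7.0), fs=1024)
        out = resample_to_1024(seg)
        assert out is seg

    def test_512_doubles_length_and_keeps_tone(self):
        fs = 512
        t = np.arange(fs * 4) / fs
        seg = EcgSegment(samples=np.sin(2 * np.pi * 5.0 * t), fs=fs)
        out = resample_to_1024(seg)
        assert out.fs == 1024
        assert out.samples.size == 2 * seg.samples.size
        spec = np.abs(np.fft.rfft(out.samples))
        freqs = np.fft.rfftfreq(out.samples.size, 1 / 1024)
        assert freqs[np.argmax(spec)] == pytest.approx(5.0, abs=0.3)

    def test_128_gives_8x_length(self):
        seg = EcgSegment(samples=np.zeros(128 * 3), fs=128)
        assert resample_to_1024(seg).samples.size == 128 * 3 * 8

    def test_unsupported_rate(self):
        seg = EcgSegment(samples=np.zeros(1000), fs=333.3)
        with pytest.raises(ValueError):
            resample_to_1024(seg)


class TestDetectRPeaks:
    def test_synthetic_120bpm_all_matched_within_10ms(self, proto_vec):
        spec = SynthSpec(target_snr_db=15.0, mean_rr_s=0.5, rr_jitter_s=0.02)
        vecs = np.tile(proto_vec, (120, 1))
        seg, truth = render_trace(vecs, spec, np.random.default_rng(3))
        det = detect_r_peaks(seg)
        matched = sum(np.min(np.abs(det - t)) <= 0.010 for t in truth)
        assert matched / truth.size >= 0.99
        assert abs(det.size - truth.size) <= 1

    def test_flat_signal_rejected(self):
        seg = EcgSegment(samples=np.zeros(1024 * 30), fs=1024)
        with pytest.raises(SegmentRejected):
            detect_r_peaks(seg)

    def test_nineteen_beats_rejected(self, proto_vec):
        spec = SynthSpec(target_snr_db=None, mean_rr_s=0.5)
        seg, _ = render_trace(
            np.tile(proto_vec, (19, 1)), spec, np.random.default_rng(4)
        )
        with pytest.raises(SegmentRejected, match="< 20"):
            detect_r_peaks(seg)


class TestEpochBeats:
    def test_n_peaks_give_n_minus_2_epochs(self, clean_trace):
        seg, r_times = clean_trace
        epochs = epoch_beats(seg, r_times)
        assert len(epochs) == r_times.size - 2
        assert all(e.x.shape == (500,) for e in epochs)

    def test_fewer_than_three_peaks_gives_empty(self, clean_trace):
        seg, r_times = clean_trace
        assert epoch_beats(seg, r_times[:2]) == []

    def test_constant_signal_gives_constant_epochs(self):
        seg = EcgSegment(samples=np.full(1024 * 10, 7.0), fs=1024)
        epochs = epoch_beats(seg, np.arange(0.5, 9.5, 0.5))
        assert all(np.all(e.x == 7.0) for e in epochs)

    def test_r_maximum_lands_at_normalized_zero(self, clean_trace):
        seg, r_times = clean_trace
        e = epoch_beats(seg, r_times)[5]
        # index 250 is normalized time 0 (the own R peak); restrict the
        # argmax to the interior since x[0] sits on the previous R peak
        assert abs(100 + int(np.argmax(e.x[100:400])) - 250) <= 2

    def test_alpha_definition(self):
        e = BeatEpoch(x=np.zeros(500), t1=1.0, t2=1.6, t3=2.0)
        assert e.alpha == pytest.approx(0.5 * (2.0 - 1.0))

    def test_round_trip_snr_interpolation_only(self, proto_vec):
        # isolate one beat (zero-amplitude neighbors) so the epoch window is
        # free of neighboring-beat waves; constant RR so the piecewise time
        # warp matches the uniform alpha scaling
        spec = SynthSpec(target_snr_db=None, mean_rr_s=0.5, rr_jitter_s=0.0)
        vecs = np.tile(proto_vec, (5, 1))
        silent = proto_vec.copy()
        silent[3::4] = 0.0
        vecs[[0, 1, 3, 4]] = silent
        seg, r_times = render_trace(vecs, spec, np.random.default_rng(5))
        e = epoch_beats(seg, r_times)[1]  # the live middle beat
        direct = synthesize_vector(proto_vec, GRID)
        assert snr_db(e.x, direct) >= 40.0


class TestSnrDb:
    def test_equal_noise_power_is_zero_db(self, rng):
        ref = rng.standard_normal(500)
        noise = rng.standard_normal(500)
        noise *= np.sqrt(np.sum(ref**2) / np.sum(noise**2))
        assert snr_db(ref + noise, ref) == pytest.approx(0.0, abs=1e-9)

    def test_power_ratio_semantics(self, rng):
        ref = rng.standard_normal(500)
        noise = rng.standard_normal(500)
        # noise amplitude 10^2 smaller => power 10^4 smaller => 40 dB
        n40 = noise * np.sqrt(np.sum(ref**2) / np.sum(noise**2)) / 100.0
        assert snr_db(ref + n40, ref) == pytest.approx(40.0, abs=1e-9)
        # noise power 10^2 smaller => 20 dB
        n20 = noise * np.sqrt(np.sum(ref**2) / np.sum(noise**2)) / 10.0
        assert snr_db(ref + n20, ref) == pytest.approx(20.0, abs=1e-9)

    def test_perfect_fit_is_capped(self, rng):
        ref = rng.standard_normal(500)
        assert snr_db(ref, ref) == 120.0

    def test_zero_reference_raises(self):
        with pytest.raises(UndefinedSnrError):
            snr_db(np.ones(500), np.zeros(500))

    def test_invariant_to_common_rescaling(self, rng):
        ref = rng.standard_normal(500)
        x = ref + 0.1 * rng.standard_normal(500)
        assert snr_db(3.7 * x, 3.7 * ref) == pytest.approx(snr_db(x, ref))


class TestSegmentQuality:
    def _epochs_from(self, rows):
        return [
            BeatEpoch(x=row, t1=0.0, t2=0.5, t3=1.0, beat_id=f"s:{i}")
            for i, row in enumerate(rows)
        ]

    def test_identical_epochs_hit_the_cap(self, rng):
        row = rng.standard_normal(500)
        q = segment_quality(self._epochs_from([row] * 5))
        assert np.all(q.snr_per_beat_db == 120.0)
        assert q.snr_bar_db == 120.0
        assert q.n_beats == 5

    def test_symmetric_deviation_gives_zero_db(self, rng):
        mean = rng.standard_normal(500)
        d = rng.standard_normal(500)
        d *= np.sqrt(np.sum(mean**2) / np.sum(d**2))
        q = segment_quality(self._epochs_from([mean + d, mean - d]))
        assert q.snr_bar_db == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(q.mean_beat, mean)

    def test_generator_calibration_at_10db(self, proto_vec):
        spec = SynthSpec(target_snr_db=10.0, mean_rr_s=0.5)
        seg, r_times = render_trace(
            np.tile(proto_vec, (60, 1)), spec, np.random.default_rng(6)
        )
        q = segment_quality(epoch_beats(seg, r_times))
        assert q.snr_bar_db == pytest.approx(10.0, abs=1.0)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            segment_quality([])


class TestFilterSegments:
    def _quality(self, snr):
        from lognecg.preprocess import SegmentQuality

        return SegmentQuality(
            mean_beat=np.zeros(500), snr_per_beat_db=np.array([snr]),
            snr_bar_db=snr, n_beats=1, segment_id=f"snr{snr}",
        )

    def test_threshold_is_inclusive(self):
        kept, rejected = filter_segments([self._quality(5.0)])
        assert len(kept) == 1 and not rejected

    def test_just_below_threshold_rejected(self):
        kept, rejected = filter_segments([self._quality(4.99)])
        assert not kept and len(rejected) == 1

    def test_mixed_synthetic_batch(self, proto_vec):
        quals = []
        for i, target in enumerate((-5.0, 0.0, 5.0, 10.0)):
            spec = SynthSpec(target_snr_db=target, mean_rr_s=0.5)
            seg, r_times = render_trace(
                np.tile(proto_vec, (40, 1)), spec, np.random.default_rng(10 + i)
            )
            quals.append(
                segment_quality(epoch_beats(seg, r_times), segment_id=str(target))
            )
        kept, rejected = filter_segments(quals)
        assert {q.segment_id for q in kept} == {"5.0", "10.0"}
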