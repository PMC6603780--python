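"""Heart-sound HSMM segmentation and sphygmogram template matching."""

import numpy as np
import pytest

from radarvitals.filtering import FilterSpec, design_butterworth, extract_bands
from radarvitals.heartbeat import (
    BeatTimes,
    IbiSeries,
    S1,
    _PREV_STATE,
    beats_from_segmentation,
    build_hsmm_model,
    default_emissions,
    detect_heartbeats_hsmm,
    estimate_heart_cycle,
    extract_features,
    hsmm_segment,
    ibi,
    ibi_rmse,
    template_match_beats,
)
from radarvitals.reconstruction import reconstruct
from radarvitals.signals import DisplacementTrace
from radarvitals.simulator import ChannelConfig, VitalMotionConfig, synth_displacement, synth_quadrature
from scipy import signal as sps


def heartsound_band(x, fs=2000.0):
    sos = design_butterworth(FilterSpec("bandpass", (16.0, 80.0)), fs)
    return DisplacementTrace(displacement_um=sps.sosfiltfilt(sos, x), sample_rate=fs)


def synthetic_pcg(heart_rate=60.0, duration=30.0, seed=0, jitter=0.0, noise_um=1.07):
    cfg = VitalMotionConfig(
        duration_s=duration, heart_rate=heart_rate, heart_rate_jitter=jitter
    )
    truth = synth_displacement(cfg, seed=seed)
    rng = np.random.default_rng(seed + 5000)
    noisy = truth.displacement_um + noise_um * rng.standard_normal(truth.n)
    return heartsound_band(noisy), truth


class TestFeatures:
    def test_single_burst_envelopes_unimodal(self):
        fs = 2000.0
        t = np.arange(int(10 * fs)) / fs
        x = 50.0 * np.exp(-0.5 * ((t - 5.0) / 0.012) ** 2) * np.cos(2 * np.pi * 40 * (t - 5.0))
        feats = extract_features(DisplacementTrace(displacement_um=x, sample_rate=fs))
        for col in range(3):
            peak_t = feats.frame_times()[np.argmax(feats.matrix[:, col])]
            assert peak_t == pytest.approx(5.0, abs=1.0 / 50.0 + 0.01)

    def test_twin_bursts_equal_peak_heights(self):
        fs = 2000.0
        t = np.arange(int(10 * fs)) / fs
        x = np.zeros_like(t)
        for c in (3.0, 7.0):
            x += 50.0 * np.exp(-0.5 * ((t - c) / 0.012) ** 2) * np.cos(2 * np.pi * 40 * (t - c))
        feats = extract_features(DisplacementTrace(displacement_um=x, sample_rate=fs))
        ft = feats.frame_times()
        h = feats.matrix[:, 0]
        p1 = h[(ft > 2.0) & (ft < 4.0)].max()
        p2 = h[(ft > 6.0) & (ft < 8.0)].max()
        assert p1 == pytest.approx(p2, rel=0.01)

    def test_envelope_peaks_match_truth_burst_centers(self):
        hs, truth = synthetic_pcg(heart_rate=60.0, seed=2)
        feats = extract_features(hs)
        ft = feats.frame_times()
        h = feats.matrix[:, 0]
        for c in truth.meta["s1_centers"][2:5]:
            sel = (ft > c - 0.2) & (ft < c + 0.2)
            assert ft[sel][np.argmax(h[sel])] == pytest.approx(c, abs=0.02)

    def test_short_record_rejected(self):
        with pytest.raises(ValueError, match="3 s"):
            extract_features(DisplacementTrace(displacement_um=np.zeros(1000), sample_rate=2000.0))


class TestHeartCycle:
    @pytest.mark.parametrize("hr,cycle", [(60.0, 1.0), (90.0, 60.0 / 90.0)])
    def test_cycle_recovered(self, hr, cycle):
        hs, _ = synthetic_pcg(heart_rate=hr, seed=3)
        est_cycle, est_sys = estimate_heart_cycle(extract_features(hs))
        assert est_cycle == pytest.approx(cycle, abs=0.02)
        assert 0.2 * est_cycle <= est_sys <= 0.5 * est_cycle

    def test_white_noise_rejected(self):
        rng = np.random.default_rng(0)
        hs = heartsound_band(rng.standard_normal(60000))
        with pytest.raises(ValueError, match="periodicity|signal quality"):
            estimate_heart_cycle(extract_features(hs))


class TestHsmm:
    def test_clean_pcg_onsets_near_truth(self):
        hs, truth = synthetic_pcg(heart_rate=60.0, duration=10.0, seed=4, noise_um=0.0)
        beats = detect_heartbeats_hsmm(hs)
        tb = truth.meta["s1_centers"]
        assert beats.times.size == tb.size
        # S1 onset leads the wavelet centre by about half the S1 duration
        offsets = beats.times - (tb - 0.06)
        assert np.all(np.abs(offsets) < 0.03)

    def test_noisy_pcg_most_onsets_recovered(self):
        hs, truth = synthetic_pcg(heart_rate=70.0, duration=10.0, seed=5, noise_um=5.0)
        beats = detect_heartbeats_hsmm(hs)
        tb = truth.meta["s1_centers"]
        hits = sum(np.any(np.abs(t - (tb - 0.06)) < 0.05) for t in beats.times)
        assert hits >= tb.size - 1

    def test_state_sequence_respects_cyclic_order(self):
        hs, _ = synthetic_pcg(heart_rate=75.0, seed=6)
        feats = extract_features(hs)
        cycle, systole = estimate_heart_cycle(feats)
        model = build_hsmm_model(cycle, systole, default_emissions())
        seg = hsmm_segment(feats, model)
        labels = seg.labels
        changes = np.flatnonzero(np.diff(labels) != 0)
        for i in changes:
            assert _PREV_STATE[labels[i + 1]] == labels[i]

    def test_matched_duration_model_scores_higher(self):
        """The decoder's likelihood drops under a mismatched cycle prior."""
        hs, _ = synthetic_pcg(heart_rate=60.0, seed=7)
        feats = extract_features(hs)
        emissions = default_emissions()
        good = hsmm_segment(feats, build_hsmm_model(1.0, 0.3, emissions))
        bad = hsmm_segment(feats, build_hsmm_model(0.55, 0.18, emissions))
        assert good.log_likelihood > bad.log_likelihood

    def test_silence_yields_no_beats_after_gating(self):
        sil = DisplacementTrace(displacement_um=np.zeros(60000), sample_rate=2000.0)
        feats = extract_features(sil)
        seg = hsmm_segment(feats, build_hsmm_model(1.0, 0.3, default_emissions()))
        assert beats_from_segmentation(seg).times.size == 0

    def test_dimension_mismatch_rejected(self):
        hs, _ = synthetic_pcg(seed=8, duration=5.0)
        feats = extract_features(hs)
        means, covs = default_emissions()
        model = build_hsmm_model(1.0, 0.3, (means[:, :2], covs[:, :2, :2]))
        with pytest.raises(ValueError, match="dimension"):
            hsmm_segment(feats, model)


class TestTemplateMatching:
    def sphygmogram(self, seed=9, duration=30.0, **kwargs):
        cfg = VitalMotionConfig(duration_s=duration, heart_rate=60.0, **kwargs)
        truth = synth_displacement(cfg, seed=seed)
        rec = reconstruct(synth_quadrature(truth, ChannelConfig(), seed=seed + 1))
        return extract_bands(rec).sphygmogram, truth

    def test_clean_pulse_train_one_beat_per_second(self):
        # sinusoidal breathing has no harmonics inside the 0.75-5 Hz band,
        # so the pulse train is the only in-band content
        sph, truth = self.sphygmogram(
            heart_rate_jitter=0.0,
            pulse_transit_jitter_s=0.0,
            pulse_amplitude_jitter=0.0,
            respiration_waveform="sinusoid",
            body_motion_rms_um=0.0,
        )
        beats = template_match_beats(sph)
        tb = truth.meta["beat_times"]
        assert abs(beats.times.size - tb.size) <= 1
        intervals = np.diff(beats.times)
        assert np.abs(intervals - 1.0).max() < 0.02

    def test_amplitude_modulation_does_not_shift_beats(self):
        """Normalized correlation is insensitive to slow amplitude changes."""
        sph, _ = self.sphygmogram(
            heart_rate_jitter=0.0, pulse_transit_jitter_s=0.0, pulse_amplitude_jitter=0.0
        )
        base = template_match_beats(sph)
        t = np.arange(sph.n) / sph.sample_rate
        mod = DisplacementTrace(
            displacement_um=sph.displacement_um * (1.0 + 0.4 * np.sin(2 * np.pi * t / 40.0)),
            sample_rate=sph.sample_rate,
        )
        modded = template_match_beats(mod)
        n = min(base.times.size, modded.times.size)
        assert np.abs(base.times[:n] - modded.times[:n]).max() < 0.02

    def test_flat_signal_rejected(self):
        flat = DisplacementTrace(displacement_um=np.zeros(3000), sample_rate=100.0)
        with pytest.raises(ValueError, match="flat|periodicity"):
            template_match_beats(flat)


class TestIbi:
    def test_first_differences(self):
        series = ibi(BeatTimes(times=np.array([1.0, 2.0, 3.0])))
        np.testing.assert_allclose(series.intervals, [1.0, 1.0])
        assert not series.implausible.any()

    def test_single_beat_empty(self):
        assert ibi(BeatTimes(times=np.array([1.0]))).intervals.size == 0

    def test_implausible_interval_flagged(self):
        series = ibi(BeatTimes(times=np.array([1.0, 1.1, 2.1])))
        assert series.implausible.tolist() == [True, False]

    def test_translation_equivariance(self):
        a = BeatTimes(times=np.array([0.5, 1.4, 2.2]))
        b = BeatTimes(times=a.times + 17.3)
        np.testing.assert_allclose(ibi(a).intervals, ibi(b).intervals)

    def test_rmse_identical_zero(self):
        s = IbiSeries(intervals=np.array([0.8, 0.9]))
        assert ibi_rmse(s, s) == 0.0

    def test_rmse_hand_computed(self):
        pred = IbiSeries(intervals=np.array([0.85, 0.75]))
        ref = IbiSeries(intervals=np.array([0.80, 0.80]))
        assert ibi_rmse(pred, ref) == pytest.approx(50.0)

    def test_rmse_single_pair_identity(self):
        pred = IbiSeries(intervals=np.array([0.80000]))
        ref = IbiSeries(intervals=np.array([0.82607]))
        assert ibi_rmse(pred, ref) == pytest.approx(26.07, abs=1e-9)

    def test_rmse_empty_rejected(self):
        with pytest.raises(ValueError):
            ibi_rmse(IbiSeries(intervals=np.array([])), IbiSeries(intervals=np.array([])))
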