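"""Synthetic-EEG generator: noise spectra, injections, artifacts, determinism."""

import numpy as np
import pytest
from dataclasses import replace

from stereoattn import (ContinuousRecording, ErpComponentSpec, GroundTruth,
                        gaussian_topography, generate_pink_noise,
                        generate_subject, generate_trial_schedule, inject_erp,
                        inject_ocular_artifacts, inject_ssvep)
from stereoattn.simulate import simulate_presses


def _blank_recording(montage, n_samples=512 * 8):
    data = np.zeros((len(montage.labels), n_samples), dtype=np.float32)
    return ContinuousRecording(data=data, rate=512.0, montage=montage)


class TestPinkNoise:
    def test_power_slope_matches_exponent(self):
        from scipy.signal import welch

        x = generate_pink_noise(512 * 60, 4, exponent=1.0, rms_uv=10.0, seed=0)
        f, p = welch(x.astype(float), fs=512, nperseg=4096, axis=1)
        sel = (f >= 1) & (f <= 100)
        slope = np.polyfit(np.log10(f[sel]), np.log10(p[:, sel].mean(0)), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.2)

    def test_white_when_exponent_zero(self):
        from scipy.signal import welch

        x = generate_pink_noise(512 * 30, 2, exponent=0.0, rms_uv=5.0, seed=1)
        f, p = welch(x.astype(float), fs=512, nperseg=2048, axis=1)
        sel = (f >= 1) & (f <= 100)
        slope = np.polyfit(np.log10(f[sel]), np.log10(p[:, sel].mean(0)), 1)[0]
        assert abs(slope) < 0.1

    def test_rms_exact_and_zero_case(self):
        x = generate_pink_noise(512 * 10, 3, exponent=1.0, rms_uv=7.0, seed=2)
        assert np.sqrt((x.astype(float) ** 2).mean(axis=1)) == pytest.approx(
            np.full(3, 7.0), rel=1e-4)
        assert not generate_pink_noise(100, 2, rms_uv=0.0).any()


class TestInjectSsvep:
    def test_zero_envelope_is_identity(self, montage):
        rec = _blank_recording(montage)
        inject_ssvep(rec, 15.0, np.zeros(rec.n_samples),
                     np.ones(montage.n_scalp), 1.0)
        assert not rec.data.any()

    def test_fft_amplitude_matches_injection(self, montage):
        rec = _blank_recording(montage, 512 * 4)
        topo = np.zeros(montage.n_scalp)
        oz = montage.index("Oz")
        topo[oz] = 1.0
        inject_ssvep(rec, 15.0, np.ones(rec.n_samples), topo, 1.0)
        spec = 2 * np.abs(np.fft.rfft(rec.data[oz].astype(float))) / rec.n_samples
        freqs = np.fft.rfftfreq(rec.n_samples, 1 / 512)
        assert spec[np.argmin(np.abs(freqs - 15))] == pytest.approx(1.0, rel=1e-3)

    def test_additivity(self, montage):
        env = np.ones(512)
        topo = np.ones(montage.n_scalp)
        a = _blank_recording(montage, 512)
        inject_ssvep(a, 15.0, env, topo, 1.0)
        inject_ssvep(a, 15.0, env, topo, 1.0)
        b = _blank_recording(montage, 512)
        inject_ssvep(b, 15.0, env, topo, 2.0)
        assert np.allclose(a.data, b.data, atol=1e-5)

    def test_above_nyquist_raises(self, montage):
        rec = _blank_recording(montage, 512)
        with pytest.raises(ValueError):
            inject_ssvep(rec, 300.0, np.ones(512), np.ones(montage.n_scalp), 1.0)


class TestInjectErp:
    SPEC = ErpComponentSpec("sn", center_ms=275.0, width_ms=200.0,
                            amp_attended_uv=-2.0, amp_ignored_uv=0.0,
                            topo_centers=("PO7", "PO8"))

    def test_zero_amplitude_is_identity(self, montage):
        rec = _blank_recording(montage)
        inject_erp(rec, np.array([1000]), self.SPEC, np.array([0.0]))
        assert not rec.data.any()

    def test_peak_sign_and_latency(self, montage):
        rec = _blank_recording(montage)
        inject_erp(rec, np.array([1024]), self.SPEC, np.array([-2.0]))
        ch = montage.index("PO7")
        trace = rec.data[ch].astype(float)
        window = trace[1024 + int(0.200 * 512):1024 + int(0.350 * 512)]
        assert window.mean() < 0
        peak_at = np.argmin(trace) - 1024
        assert peak_at / 512 * 1000 == pytest.approx(275, abs=4)

    def test_average_recovers_peak_in_noise(self, montage):
        # 300 events in 1/f noise: the evoked average reads back the
        # injected peak at its programmed latency within 10 %
        rng = np.random.default_rng(11)
        spacing = 1100
        n = 300 * spacing + 512
        rec = ContinuousRecording(
            data=generate_pink_noise(n, len(montage.labels), 1.0, 1.5, rng),
            rate=512.0, montage=montage)
        events = np.arange(100, 300 * spacing, spacing)
        inject_erp(rec, events, self.SPEC, np.full(events.size, -2.0))
        ch = montage.index("PO7")
        epochs = np.stack([rec.data[ch, e:e + 300].astype(float) for e in events])
        evoked = (epochs - epochs[:, :50].mean(axis=1, keepdims=True)).mean(0)
        peak_idx = int(round(0.275 * 512))
        w_po7 = gaussian_topography(montage, self.SPEC.topo_centers,
                                    self.SPEC.topo_sigma_rad)[
            montage.scalp_labels.index("PO7")]
        assert evoked[peak_idx] == pytest.approx(-2.0 * w_po7, abs=0.1)


class TestArtifacts:
    def test_zero_rates_identity(self, montage):
        rec = _blank_recording(montage)
        table = inject_ocular_artifacts(rec, 0.0, 0.0, seed=0)
        assert len(table) == 0 and not rec.data.any()

    def test_blink_amplitudes_within_bounds(self, montage):
        rec = _blank_recording(montage, 512 * 600)
        table = inject_ocular_artifacts(rec, 100.0, 0.0, seed=1)
        blinks = table[table.kind == "blink"]
        assert len(blinks) > 500
        assert blinks.amp_uv.between(200, 400).all()
        durs = (blinks.stop - blinks.start) / 512 * 1000
        assert durs.between(99, 201).all()

    def test_saccade_steps_on_heog(self, montage):
        rec = _blank_recording(montage, 512 * 300)
        table = inject_ocular_artifacts(rec, 0.0, 30.0, seed=2)
        sac = table[table.kind == "saccade"]
        assert len(sac) > 50
        assert (sac.amp_uv.abs() >= 30).all()
        heog = rec.data[montage.index("HEOG")]
        row = sac.iloc[0]
        assert abs(heog[(row.start + row.stop) // 2]) >= 30


class TestGenerateSubject:
    def test_deterministic_for_fixed_seed(self, small_schedule, ground_truth,
                                          montage):
        r1, t1, p1 = generate_subject(small_schedule, ground_truth, montage,
                                      seed=5)
        r2, t2, p2 = generate_subject(small_schedule, ground_truth, montage,
                                      seed=5)
        assert np.array_equal(r1.data, r2.data)
        assert r1.markers == r2.markers
        assert p1 == p2

    def test_marker_counts_match_schedule(self, small_recording, small_schedule):
        rec, truth, presses = small_recording
        cues = [m for m in rec.markers if m[1].startswith("cue:")]
        events = [m for m in rec.markers if m[1].startswith("event:")]
        assert len(cues) == len(small_schedule)
        assert len(events) == small_schedule.n_events

    def test_envelope_ground_truth_recoverable(self, ground_truth):
        t = np.arange(-1000.0, 2000.0, 10.0)
        env = ground_truth.envelope("attended", t)
        assert np.allclose(env[t < 0], 1.0)
        assert env[-1] == pytest.approx(ground_truth.attended_level, abs=1e-3)

    def test_press_rates_within_binomial_bounds(self):
        sched = generate_trial_schedule(960, (480, 240, 240), seed=4)
        gt = GroundTruth()
        presses = simulate_presses(sched, gt.p_hit, gt.p_fa, seed=8)
        recs = sched.event_records()
        n_att = sum(r["attended"] for r in recs)
        n_ign = len(recs) - n_att
        # count presses near attended/ignored events
        from stereoattn.behavior import classify_responses

        events, _ = classify_responses(sched, presses)
        hits = (events.outcome == "hit").sum()
        fas = (events.outcome == "false_alarm").sum()
        for k, n, p in ((hits, n_att, gt.p_hit), (fas, n_ign, gt.p_fa)):
            se = np.sqrt(n * p * (1 - p))
            assert abs(k - n * p) < 3.5 * se


def test_topography_peaks_at_center(montage):
    w = gaussian_topography(montage, ("Oz",), 0.6)
    assert w.max() == pytest.approx(1.0)
    assert w[montage.scalp_labels.index("Oz")] == pytest.approx(1.0)
    assert w[montage.scalp_labels.index("Fpz")] < 0.2
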