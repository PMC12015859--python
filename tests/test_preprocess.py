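"""Artifact rejection chain, spline interpolation and surface Laplacian."""

import numpy as np
import pandas as pd
import pytest
from numpy.polynomial import legendre

from stereoattn import (ContinuousRecording, EpochSet, detect_blinks,
                        detect_saccades, extract_epochs, remove_dc,
                        rereference_average, scan_channel_contamination,
                        spherical_spline_interpolate, surface_laplacian)
from stereoattn.preprocess import KEPT, REJ_CHAN


def _epochs(montage, data, window=(-1000.0, 2000.0), rate=512.0):
    return EpochSet(data=np.asarray(data, dtype=np.float32), window_ms=window,
                    rate=rate, montage=montage)


def _rand_epochs(montage, n_epochs=16, n_samp=256, seed=0, scale=10.0):
    rng = np.random.default_rng(seed)
    data = rng.normal(0, scale, (n_epochs, len(montage.labels), n_samp))
    return _epochs(montage, data, window=(0.0, n_samp / 512.0 * 1000.0))


class TestRemoveDc:
    def test_constant_channel_zeroed(self, montage):
        data = np.full((len(montage.labels), 1000), 3.5, dtype=np.float32)
        rec = ContinuousRecording(data=data, rate=512.0, montage=montage)
        remove_dc(rec)
        assert np.allclose(rec.data, 0.0, atol=1e-5)

    def test_output_means_negligible(self, montage):
        rng = np.random.default_rng(1)
        data = rng.normal(5, 2, (len(montage.labels), 4096)).astype(np.float32)
        rec = ContinuousRecording(data=data, rate=512.0, montage=montage)
        remove_dc(rec)
        assert np.abs(rec.data.mean(axis=1)).max() < 1e-4  # float32 rounding


class TestExtractEpochs:
    def test_sample_arithmetic(self, montage):
        n = 512 * 30
        rec = ContinuousRecording(
            data=np.zeros((len(montage.labels), n), dtype=np.float32),
            rate=512.0, montage=montage)
        ep = extract_epochs(rec, np.array([512 * 5, 512 * 10]), (-1000.0, 2000.0))
        assert ep.data.shape[2] == 1536          # 3 s at 512 Hz
        t = ep.times_ms
        anchor_idx = np.argmin(np.abs(t))
        assert t[anchor_idx] == pytest.approx(0.0, abs=1e-9)
        assert anchor_idx == 512

    def test_edge_anchors_dropped(self, montage):
        rec = ContinuousRecording(
            data=np.zeros((len(montage.labels), 512 * 5), dtype=np.float32),
            rate=512.0, montage=montage)
        ep = extract_epochs(rec, np.array([0, 512 * 2]), (-1000.0, 2000.0))
        assert ep.n_epochs == 1
        assert ep.n_dropped_edge == 1

    def test_empty_anchor_list(self, montage):
        rec = ContinuousRecording(
            data=np.zeros((len(montage.labels), 512 * 5), dtype=np.float32),
            rate=512.0, montage=montage)
        ep = extract_epochs(rec, np.array([], dtype=int), (-100.0, 700.0))
        assert ep.n_epochs == 0


class TestBlinkDetection:
    def test_quiet_veog_no_flags(self, montage):
        ep = _rand_epochs(montage, seed=2, scale=5.0)
        flags = detect_blinks(ep)
        assert not flags.any()

    def test_injected_blinks_flagged(self, montage):
        ep = _rand_epochs(montage, n_epochs=40, seed=3, scale=8.0)
        iv = montage.index("VEOG")
        blink_epochs = [3, 11, 19, 27]
        for e in blink_epochs:
            ep.data[e, iv, 100:160] += 300.0
        flags = detect_blinks(ep)
        assert set(np.flatnonzero(flags)) == set(blink_epochs)

    def test_threshold_floor_respected(self, montage):
        # tiny VEOG fluctuations below the floor are never flagged
        ep = _rand_epochs(montage, seed=4, scale=0.1)
        iv = montage.index("VEOG")
        ep.data[:, iv, :] = np.random.default_rng(0).normal(
            0, 0.5, ep.data[:, iv, :].shape)
        assert not detect_blinks(ep, floor_uv=60.0).any()

    def test_missing_channel_raises(self, montage):
        ep = _rand_epochs(montage)
        with pytest.raises(ValueError):
            detect_blinks(ep, veog_channel="NOPE")


class TestSaccadeDetection:
    @pytest.mark.parametrize("step,expect", [(40.0, True), (20.0, False)])
    def test_step_threshold(self, montage, step, expect):
        ep = _rand_epochs(montage, seed=5, scale=1.0)
        ih = montage.index("HEOG")
        ep.data[2, ih, 128:] += step
        flags = detect_saccades(ep, step_uv=30.0)
        assert flags[2] == expect
        assert not flags[[0, 1, 3]].any()


class TestContaminationScan:
    def test_homogeneous_rate_low(self, montage):
        ep = _rand_epochs(montage, n_epochs=60, n_samp=512, seed=6)
        flags, rejected = scan_channel_contamination(ep)
        assert flags.mean() < 0.02
        assert not rejected.any()

    def test_single_bad_channel_epoch_flagged(self, montage):
        ep = _rand_epochs(montage, n_epochs=30, seed=7)
        ep.data[4, 10, :] *= 10.0
        flags, rejected = scan_channel_contamination(ep)
        assert flags[4, 10]
        assert 10 in ep.interpolated[4]

    def test_cap_rule_rejects_epoch(self, montage):
        ep = _rand_epochs(montage, n_epochs=30, seed=8)
        ep.data[5, :13, :] *= 20.0
        flags, rejected = scan_channel_contamination(ep, cap=12)
        assert rejected[5]
        assert ep.status[5] == REJ_CHAN

    def test_too_few_epochs_raises(self, montage):
        ep = _rand_epochs(montage, n_epochs=4)
        with pytest.raises(ValueError):
            scan_channel_contamination(ep)


def _harmonic_potential(montage, degree):
    """Zonal spherical harmonic P_n(z') about a tilted axis."""
    axis = np.array([0.3, -0.2, 0.93])
    axis /= np.linalg.norm(axis)
    z = montage.positions @ axis
    c = np.zeros(degree + 1)
    c[degree] = 1.0
    return legendre.legval(z, c)


class TestSplineInterpolation:
    def test_constant_potential_preserved(self, montage):
        n_ch = len(montage.labels)
        data = np.full((10, n_ch, 32), 7.0, dtype=np.float32)
        ep = _epochs(montage, data, window=(0.0, 62.5))
        ep.interpolated[0] = {5, 20}
        spherical_spline_interpolate(ep)
        assert np.allclose(ep.data[0, [5, 20]], 7.0, atol=1e-3)

    def test_leave_one_out_on_smooth_potential(self, montage):
        v = _harmonic_potential(montage, 3)
        n_ch = len(montage.labels)
        data = np.zeros((1, n_ch, 1), dtype=np.float32)
        data[0, :montage.n_scalp, 0] = v
        for ch in (10, 30, 50):
            ep = _epochs(montage, data.copy(), window=(0.0, 100.0))
            ep.interpolated[0] = {ch}
            spherical_spline_interpolate(ep)
            err = abs(ep.data[0, ch, 0] - v[ch]) / (np.abs(v).max())
            assert err < 0.05

    def test_empty_bad_set_is_identity(self, montage):
        ep = _rand_epochs(montage, n_epochs=9)
        before = ep.data.copy()
        spherical_spline_interpolate(ep)
        assert np.array_equal(ep.data, before)


class TestAverageReference:
    def test_identical_channels_become_zero(self, montage):
        n_ch = len(montage.labels)
        data = np.tile(np.sin(np.arange(64) / 3.0), (4, n_ch, 1))
        ep = _epochs(montage, data, window=(0.0, 125.0))
        rereference_average(ep)
        assert np.allclose(ep.data[:, :montage.n_scalp], 0.0, atol=1e-5)

    def test_idempotent_and_zero_mean(self, montage):
        ep = _rand_epochs(montage, n_epochs=6)
        rereference_average(ep)
        means = ep.data[:, :montage.n_scalp].mean(axis=1)
        assert np.abs(means).max() < 1e-4
        once = ep.data.copy()
        rereference_average(ep)
        assert np.allclose(ep.data, once, atol=1e-5)


class TestSurfaceLaplacian:
    def test_uniform_potential_maps_to_zero(self, montage):
        n_ch = len(montage.labels)
        data = np.full((2, n_ch, 8), 5.0, dtype=np.float32)
        ep = _epochs(montage, data, window=(0.0, 15.6))
        surface_laplacian(ep)
        scale = np.abs(ep.data).max()
        assert scale < 1e-2 * 5.0 / 0.085**2    # tiny vs a unit-scale CSD

    @pytest.mark.parametrize("degree", [2, 3])
    def test_harmonic_eigenpattern(self, montage, degree):
        """A degree-n harmonic maps onto ~n(n+1)/r^2 times itself."""
        v = _harmonic_potential(montage, degree)
        v = v - v.mean()
        n_ch = len(montage.labels)
        data = np.zeros((1, n_ch, 1), dtype=np.float32)
        data[0, :montage.n_scalp, 0] = v
        ep = _epochs(montage, data, window=(0.0, 100.0))
        surface_laplacian(ep, lam=1e-7)
        out = ep.data[0, :montage.n_scalp, 0].astype(float)
        slope = (out @ v) / (v @ v)
        expected = degree * (degree + 1) / 0.085**2
        assert slope == pytest.approx(expected, rel=0.1)
        # pattern similarity (64-electrode sampling limits fidelity at n = 3)
        r = np.corrcoef(out, v)[0, 1]
        assert r > 0.97

    def test_linearity_and_commutes_with_averaging(self, montage):
        a = _rand_epochs(montage, n_epochs=10, seed=9)
        avg_first = a.data.mean(axis=0, keepdims=True).copy()
        surface_laplacian(a)
        lap_then_avg = a.data.mean(axis=0)
        b = _epochs(montage, avg_first, window=a.window_ms)
        surface_laplacian(b)
        assert np.allclose(b.data[0], lap_then_avg, atol=1e-2 * np.abs(
            lap_then_avg).max())


class TestChainOnSyntheticSubject:
    def test_rejected_fraction_plausible(self, small_recording, small_schedule,
                                         montage):
        from stereoattn.pipeline import ssvep_subject_course
        from stereoattn import GroundTruth

        rec, truth, _ = small_recording
        rec = rec.copy()
        remove_dc(rec)
        anchors = rec.marker_samples("cue:")
        ep = extract_epochs(rec, anchors, (-1000.0, 2000.0))
        flags = detect_blinks(ep)
        ep.status[flags] = "rejected_blink"
        sacc = detect_saccades(ep)
        ep.status[sacc & (ep.status == KEPT)] = "rejected_saccade"
        scan_channel_contamination(ep)
        frac = 1.0 - ep.kept_mask.mean()
        assert 0.0 <= frac <= 0.40
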