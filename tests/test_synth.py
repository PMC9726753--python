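"""Synthetic generators: determinism, ground-truth consistency, protocol shape."""

import numpy as np
import pytest

from darksense import (REFERENCE_FLUOR, REFERENCE_SCHEME, AnnulusROI,
                       ApplicationProtocol, DiskROI, SamplingConfig,
                       apparent_kd, compute_dff, extract_roi_timeseries,
                       simulate_dose_response, simulate_invivo_session,
                       simulate_patch_sweeps, simulate_pulse_train,
                       simulate_roi_stack, steady_state)
from darksense.synth import InVivoConfig, NoiseModel

from conftest import NOISELESS


class TestPatchSweeps:
    def test_noiseless_minimum_matches_steady_state(self):
        protocol = ApplicationProtocol(concentration=1e-4, app_s=1.0,
                                       pre_s=0.5, post_s=2.0, n_sweeps=1)
        sweep = simulate_patch_sweeps(REFERENCE_SCHEME, REFERENCE_FLUOR,
                                      protocol, noise=NOISELESS)[0]
        dff = compute_dff(sweep, (0.0, 0.49))
        expected = -(1 - REFERENCE_FLUOR.epsilon) * steady_state(
            REFERENCE_SCHEME, 1e-4).f3
        assert dff.value.min() == pytest.approx(expected, rel=0.01)

    def test_seeded_determinism(self):
        protocol = ApplicationProtocol(concentration=1e-6, n_sweeps=6)
        noise = NoiseModel(gaussian_sd_frac=0.02, seed=11)
        a = simulate_patch_sweeps(REFERENCE_SCHEME, REFERENCE_FLUOR, protocol,
                                  noise=noise)
        b = simulate_patch_sweeps(REFERENCE_SCHEME, REFERENCE_FLUOR, protocol,
                                  noise=noise)
        assert len(a) == len(b) == 6
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.value, sb.value)
        # sweeps within one call differ (independent noise draws)
        assert not np.array_equal(a[0].value, a[1].value)

    def test_zero_concentration_is_flat(self):
        protocol = ApplicationProtocol(concentration=0.0, n_sweeps=1)
        sweep = simulate_patch_sweeps(REFERENCE_SCHEME, REFERENCE_FLUOR,
                                      protocol, noise=NOISELESS)[0]
        np.testing.assert_allclose(sweep.value, REFERENCE_FLUOR.f_base,
                                   atol=1e-12)

    def test_ground_truth_stored(self):
        protocol = ApplicationProtocol(concentration=1e-6, n_sweeps=1)
        sweep = simulate_patch_sweeps(REFERENCE_SCHEME, REFERENCE_FLUOR,
                                      protocol, noise=NOISELESS)[0]
        gt = sweep.annotations["ground_truth"]
        assert set(gt) == {"dff", "f3"} and len(gt["dff"]) == len(sweep)

    def test_invalid_protocol_rejected(self):
        with pytest.raises(ValueError):
            ApplicationProtocol(concentration=1e-6, app_s=0.0)
        with pytest.raises(ValueError):
            ApplicationProtocol(concentration=1e-6, n_sweeps=0)


class TestDoseResponse:
    def test_noiseless_points_on_closed_form_curve(self):
        conc = np.logspace(-8, -4, 6)
        data = simulate_dose_response(REFERENCE_SCHEME, REFERENCE_FLUOR, conc,
                                      replicates=2, noise=NOISELESS)
        for c, r in zip(data.concentration_M, data.response):
            expected = (1 - REFERENCE_FLUOR.epsilon) * steady_state(
                REFERENCE_SCHEME, c).f3
            assert r == pytest.approx(expected, rel=1e-12)

    def test_half_response_at_apparent_kd(self):
        kapp = apparent_kd(REFERENCE_SCHEME)
        data = simulate_dose_response(REFERENCE_SCHEME, REFERENCE_FLUOR,
                                      np.array([kapp, 1.0]), replicates=1,
                                      noise=NOISELESS)
        assert data.response[0] == pytest.approx(data.response[1] / 2, rel=1e-3)

    def test_default_replicate_count_is_20(self):
        data = simulate_dose_response(REFERENCE_SCHEME, REFERENCE_FLUOR,
                                      np.array([1e-7]), noise=NOISELESS)
        assert len(data.response) == 20

    def test_empty_concentrations_rejected(self):
        with pytest.raises(ValueError):
            simulate_dose_response(REFERENCE_SCHEME, REFERENCE_FLUOR,
                                   np.array([]))


class TestPulseTrain:
    def test_peak_nondecreasing_in_pulse_count(self):
        amps = []
        for n in (1, 5, 20):
            tr = simulate_pulse_train(REFERENCE_SCHEME, REFERENCE_FLUOR, n,
                                      noise=NOISELESS, internal_dt=1e-3,
                                      post_s=2.0)
            amps.append(-tr.value.min())
        assert amps[0] <= amps[1] <= amps[2]

    def test_linear_regime_for_tiny_increment(self):
        kwargs = dict(noise=NOISELESS, internal_dt=1e-3, post_s=2.0)
        a1 = -simulate_pulse_train(REFERENCE_SCHEME, REFERENCE_FLUOR, 1,
                                   per_pulse_increment=1e-9, **kwargs).value.min()
        a2 = -simulate_pulse_train(REFERENCE_SCHEME, REFERENCE_FLUOR, 1,
                                   per_pulse_increment=2e-9, **kwargs).value.min()
        assert a2 / a1 == pytest.approx(2.0, rel=0.05)

    def test_fast_clearance_kills_response(self):
        kwargs = dict(noise=NOISELESS, internal_dt=1e-3, post_s=1.0)
        slow = -simulate_pulse_train(REFERENCE_SCHEME, REFERENCE_FLUOR, 5,
                                     clearance_rate=2.0, **kwargs).value.min()
        fast = -simulate_pulse_train(REFERENCE_SCHEME, REFERENCE_FLUOR, 5,
                                     clearance_rate=1e4, **kwargs).value.min()
        assert fast < 0.05 * slow

    def test_rejects_zero_pulses(self):
        with pytest.raises(ValueError):
            simulate_pulse_train(REFERENCE_SCHEME, REFERENCE_FLUOR, 0)


class TestInVivoSession:
    def test_no_events_no_coupling_is_flat(self):
        cfg = InVivoConfig(duration_s=20, n_stim=0, reward_times=(),
                           locomotion_coupling_M=0.0,
                           noise=NOISELESS)
        s = simulate_invivo_session(cfg, REFERENCE_SCHEME, REFERENCE_FLUOR)
        assert np.ptp(s.fluorescence.value) < 1e-9

    def test_seeded_reproducibility(self):
        cfg = InVivoConfig(duration_s=30, n_stim=1, stim_start_s=10,
                           noise=NoiseModel(seed=5))
        a = simulate_invivo_session(cfg, REFERENCE_SCHEME, REFERENCE_FLUOR)
        b = simulate_invivo_session(cfg, REFERENCE_SCHEME, REFERENCE_FLUOR)
        np.testing.assert_array_equal(a.fluorescence.value, b.fluorescence.value)
        np.testing.assert_array_equal(a.speed_cm_s, b.speed_cm_s)

    def test_stim_response_is_biphasic_dip_then_overshoot(self):
        cfg = InVivoConfig(duration_s=120, n_stim=5, stim_start_s=10,
                           stim_spacing_s=20, locomotion_coupling_M=0.0,
                           run_dwell_s=1e-6, noise=NOISELESS)
        s = simulate_invivo_session(cfg, REFERENCE_SCHEME, REFERENCE_FLUOR)
        gt_dff = s.fluorescence.annotations["ground_truth"]["dff"]
        t = s.time_s
        base = np.median(gt_dff[t < 9.5])
        seg = gt_dff[(t >= 10) & (t < 28)] - base
        i_min = int(np.argmin(seg))
        assert seg[i_min] < -1e-3                 # dip: darkening on release
        assert seg[i_min:].max() > 1e-4           # later overshoot above baseline


class TestRoiStack:
    def test_zero_noise_round_trip(self):
        roi = AnnulusROI(12, 12, 4, 7)
        bg = DiskROI(30, 30, 3)
        trace = 5.0 * np.sin(np.linspace(0, 2, 40))
        stack, gt = simulate_roi_stack((48, 48), [roi], [trace],
                                       background_level=80.0, noise=NOISELESS)
        rec = extract_roi_timeseries(stack, roi, bg, rate_hz=30.3)
        np.testing.assert_allclose(rec.value, gt[0], atol=1e-10)

    def test_background_only_roi_is_flat(self):
        stack, _ = simulate_roi_stack((32, 32), [DiskROI(8, 8, 3)],
                                      [np.ones(10)], background_level=50.0,
                                      noise=NOISELESS)
        far = DiskROI(25, 25, 3)
        vals = stack[:, far.mask((32, 32))].mean(axis=1)
        np.testing.assert_allclose(vals, 50.0, atol=1e-12)

    def test_overlapping_rois_warn(self):
        with pytest.warns(UserWarning, match="overlap"):
            simulate_roi_stack((32, 32), [DiskROI(10, 10, 5), DiskROI(12, 10, 5)],
                               [np.ones(4), np.ones(4)], noise=NOISELESS)

    def test_noisy_round_trip_within_3_sd(self):
        roi = DiskROI(16, 16, 5)
        bg = DiskROI(40, 40, 5)
        trace = np.full(60, 10.0)
        noise = NoiseModel(gaussian_sd_frac=0.02, seed=2)
        stack, _ = simulate_roi_stack((48, 48), [roi], [trace],
                                      background_level=100.0, noise=noise)
        rec = extract_roi_timeseries(stack, roi, bg, rate_hz=30.3)
        n_px = int(roi.mask((48, 48)).sum())
        nb_px = int(bg.mask((48, 48)).sum())
        sd = 0.02 * 100.0 * np.sqrt(1.0 / n_px + 1.0 / nb_px)
        assert abs(rec.value.mean() - 10.0) < 3 * sd / np.sqrt(60)
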