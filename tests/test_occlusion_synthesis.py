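"""Synthetic reflectometer: envelopes, lock-in demodulation, end-to-end recovery."""

import numpy as np
import pytest

from lrbcsim.lrbc_core import LrbcConstants, lrbc_from_voltages
from lrbcsim.occlusion_synthesis import (OcclusionScenario, envelopes_from_lrbc,
                                         generate_recording, lock_in_demodulate,
                                         recording_from_envelopes)
from lrbcsim.rpf_calibration import estimate_rpf

# short but fully featured scenario for fast tests
SHORT = dict(baseline_duration=20.0, occlusion_duration=80.0, release_duration=5.0)


class TestScenarioEnvelopes:
    def test_default_drops_at_end_of_occlusion(self):
        sc = OcclusionScenario()
        t_end = sc.baseline_duration + sc.occlusion_duration - 1e-9
        assert sc.envelope(np.array([t_end]), 1.0, sc.drop_590)[0] == pytest.approx(0.75, abs=1e-6)
        assert sc.envelope(np.array([t_end]), 1.0, sc.drop_780)[0] == pytest.approx(0.97, abs=1e-6)

    def test_biphasic_initial_step(self):
        sc = OcclusionScenario(shape="biphasic", biphasic_jump_fraction=0.4, **SHORT)
        t0 = sc.baseline_duration
        just_before = sc.envelope(np.array([t0 - 0.01]), 1.0, 0.25)[0]
        just_after = sc.envelope(np.array([t0]), 1.0, 0.25)[0]
        assert just_before == pytest.approx(1.0)
        assert just_after == pytest.approx(1.0 - 0.4 * 0.25, abs=1e-6)

    def test_release_recovers_toward_baseline(self):
        sc = OcclusionScenario(recovery_time_constant=5.0, **SHORT)
        t_rel = sc.baseline_duration + sc.occlusion_duration
        late = sc.envelope(np.array([t_rel + 50.0]), 1.0, 0.25)[0]
        assert late == pytest.approx(1.0, abs=1e-4)

    def test_phase_labels(self):
        sc = OcclusionScenario(**SHORT)
        labels = sc.phase_labels(np.array([5.0, 30.0, 102.0]))
        assert list(labels) == ["baseline", "occlusion", "release"]

    def test_validation(self):
        with pytest.raises(ValueError):
            OcclusionScenario(drop_590=1.5)
        with pytest.raises(ValueError):
            OcclusionScenario(shape="triphasic")
        with pytest.raises(ValueError):
            OcclusionScenario(baseline_duration=0.0)


class TestGenerateRecording:
    def test_pure_sinusoids_when_no_drop_no_noise(self):
        sc = OcclusionScenario(drop_590=0.0, drop_780=0.0, noise_sd=0.0,
                               baseline_duration=1.0, occlusion_duration=1.0,
                               release_duration=1.0)
        rec = generate_recording(sc)
        np.testing.assert_allclose(rec.channel_590,
                                   np.sin(2 * np.pi * 1100.0 * rec.time), atol=1e-12)
        np.testing.assert_allclose(rec.channel_780,
                                   np.sin(2 * np.pi * 1000.0 * rec.time), atol=1e-12)

    def test_same_seed_bit_identical(self):
        sc = OcclusionScenario(seed=9, baseline_duration=1.0,
                               occlusion_duration=1.0, release_duration=1.0)
        a, b = generate_recording(sc), generate_recording(sc)
        np.testing.assert_array_equal(a.channel_590, b.channel_590)
        np.testing.assert_array_equal(a.channel_780, b.channel_780)

    def test_envelopes_retained(self):
        sc = OcclusionScenario(baseline_duration=1.0, occlusion_duration=1.0,
                               release_duration=1.0)
        rec = generate_recording(sc)
        assert rec.true_envelope_590 is not None
        assert len(rec.true_envelope_590) == len(rec.channel_590)


class TestLockIn:
    def test_single_tone_amplitude(self):
        """A noiseless carrier of amplitude A demodulates to A within 0.1%."""
        t = np.arange(50_000) / 50_000
        rec = recording_from_envelopes(t, 0.7 * np.ones_like(t),
                                       0.4 * np.ones_like(t), noise_sd=0.0)
        demod = lock_in_demodulate(rec)
        np.testing.assert_allclose(demod.ve_590, 0.7, rtol=1e-3)
        np.testing.assert_allclose(demod.ve_780, 0.4, rtol=1e-3)
        assert demod.rate == pytest.approx(50.0)

    def test_cross_talk_below_1e6(self):
        """Integer-cycle windows make the two carriers exactly orthogonal."""
        t = np.arange(50_000) / 50_000
        mixed = 0.5 * np.sin(2 * np.pi * 1100.0 * t) + 0.3 * np.sin(2 * np.pi * 1000.0 * t)
        rec = recording_from_envelopes(t, np.ones_like(t), np.ones_like(t))
        rec.channel_590 = mixed
        rec.channel_780 = mixed
        demod = lock_in_demodulate(rec)
        np.testing.assert_allclose(demod.ve_590, 0.5, atol=1e-6)
        np.testing.assert_allclose(demod.ve_780, 0.3, atol=1e-6)

    def test_window_constraints(self):
        t = np.arange(50_000) / 50_000
        rec = recording_from_envelopes(t, np.ones_like(t), np.ones_like(t))
        with pytest.raises(ValueError, match="divide"):
            lock_in_demodulate(rec, window_length=1024)
        with pytest.raises(ValueError, match="integer number of periods"):
            lock_in_demodulate(rec, window_length=625)  # 12.5 ms: 13.75 cycles @1100

    def test_envelope_recovery_within_noise_bound(self):
        """Demodulated envelopes track the generating ones; relative RMSE
        stays below 2 * noise_sd / sqrt(window)."""
        sc = OcclusionScenario(noise_sd=0.01, seed=4, **SHORT)
        rec = generate_recording(sc)
        demod = lock_in_demodulate(rec)
        env = sc.envelope(demod.time, sc.amplitude_590, sc.drop_590)
        rmse = np.sqrt(np.mean((demod.ve_590 / env - 1.0) ** 2))
        assert rmse < 2 * sc.noise_sd / np.sqrt(1000)


class TestEndToEnd:
    def _rpf_roundtrip(self, noise_sd, seed):
        sc = OcclusionScenario(noise_sd=noise_sd, seed=seed, **SHORT)
        rec = generate_recording(sc)
        demod = lock_in_demodulate(rec)
        est = estimate_rpf(demod, sc.inflation_time, occlusion_window=(10.0, 70.0))
        # ground truth: the same regression applied to the noiseless envelopes
        t = demod.time
        truth_demod = type(demod)(time=t,
                                  ve_590=sc.envelope(t, sc.amplitude_590, sc.drop_590),
                                  ve_780=sc.envelope(t, sc.amplitude_780, sc.drop_780),
                                  rate=demod.rate)
        truth = estimate_rpf(truth_demod, sc.inflation_time,
                             occlusion_window=(10.0, 70.0))
        return est, truth

    def test_rpf_recovery_noiseless(self):
        for seed in range(5):
            est, truth = self._rpf_roundtrip(0.0, seed)
            assert est == pytest.approx(truth, rel=0.05)

    def test_rpf_recovery_default_noise_many_seeds(self):
        errs = []
        for seed in range(22):
            est, truth = self._rpf_roundtrip(0.01, seed)
            errs.append(abs(est / truth - 1.0))
        assert np.median(errs) < 0.10
        assert np.mean(np.asarray(errs) < 0.10) > 0.8

    def test_implied_rpf_within_plausible_physiological_range(self):
        _, truth = self._rpf_roundtrip(0.0, 0)
        assert 0.8 < truth < 5.5

    def test_lrbc_ramp_slope_recovery(self):
        """Inverse-first generation: a 4 um/min LRBC ramp is recovered from
        the demodulated series within 10%."""
        constants = LrbcConstants()
        rate = 4.0  # um/min
        sc = OcclusionScenario(noise_sd=0.005, seed=11, **SHORT)
        n = int(sc.total_duration * sc.sample_rate)
        t = np.arange(n) / sc.sample_rate
        lrbc_target = 17.0 + rate / 60.0 * np.clip(t - sc.inflation_time, 0.0, None)
        env780 = sc.envelope(t, 1.0, sc.drop_780)
        env590 = envelopes_from_lrbc(lrbc_target, env780, constants)
        rec = recording_from_envelopes(t, env590, env780, noise_sd=sc.noise_sd,
                                       seed=sc.seed)
        series = lrbc_from_voltages(lock_in_demodulate(rec), constants)
        occ = (series.time >= sc.inflation_time) & (series.time <= sc.inflation_time + 60.0)
        slope = np.polyfit(series.time[occ], series.lrbc[occ], 1)[0] * 60.0
        assert slope == pytest.approx(rate, rel=0.10)
        base = series.time < sc.inflation_time
        assert np.mean(series.lrbc[base]) == pytest.approx(17.0, abs=0.5)

    def test_biphasic_series_shows_initial_jump(self):
        constants = LrbcConstants()

        def initial_rise(shape):
            sc = OcclusionScenario(shape=shape, noise_sd=0.002, seed=3, **SHORT)
            series = lrbc_from_voltages(lock_in_demodulate(generate_recording(sc)),
                                        constants)
            base = np.mean(series.lrbc[series.time < sc.inflation_time])
            after = np.mean(series.lrbc[(series.time >= sc.inflation_time + 0.5)
                                        & (series.time <= sc.inflation_time + 1.5)])
            return after - base

        assert initial_rise("biphasic") > 2.0  # near-vertical jump, um
        assert abs(initial_rise("monophasic")) < 1.0
        # and the gradual rise continues after the jump
        sc = OcclusionScenario(shape="biphasic", noise_sd=0.002, seed=3, **SHORT)
        series = lrbc_from_voltages(lock_in_demodulate(generate_recording(sc)),
                                    constants)
        early = np.mean(series.lrbc[(series.time > sc.inflation_time + 2)
                                    & (series.time < sc.inflation_time + 12)])
        late = np.mean(series.lrbc[(series.time > sc.inflation_time + 60)
                                   & (series.time < sc.inflation_time + 70)])
        assert late > early
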