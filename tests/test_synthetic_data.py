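import dataclasses

import numpy as np
import pytest

import ergflick as ef
from ergflick.errors import ConfigError, DomainError
from ergflick.protocols import build_dark_adaptation_protocol
from ergflick.synthetic_data import (
    CONDITIONS,
    DA_NIGHT,
    DEFAULT_ADAPTATION_DYNAMICS,
    DEFAULT_CONDITION_PARAMS,
    LA_DAY,
    LA_NIGHT,
)

FS = 5000.0


def measured_fundamental(rec):
    spec = ef.amplitude_spectrum(rec.samples, rec.fs)
    return spec.amplitudes[spec.bin_index(rec.stimulus.frequency)]


class TestSteadyStateAmplitude:
    def test_zero_at_the_intercept_intensity(self):
        p = ef.PhotoreceptorParams(slope_m=4.0, i0=1e-3, fc=50.0)
        assert ef.steady_state_amplitude(p, 1e-3, 0.0) == 0.0

    def test_one_log_unit_above_threshold(self):
        p = ef.PhotoreceptorParams(slope_m=4.0, i0=1e-3, fc=50.0)
        assert ef.steady_state_amplitude(p, 1e-2, 0.0) == pytest.approx(4.0, rel=1e-12)

    def test_corner_frequency_is_minus_3db(self):
        p = ef.PhotoreceptorParams(slope_m=4.0, i0=1e-3, fc=30.0)
        v0 = ef.steady_state_amplitude(p, 1e-1, 0.0)
        vfc = ef.steady_state_amplitude(p, 1e-1, 30.0)
        assert vfc == pytest.approx(v0 / np.sqrt(2), rel=1e-9)

    def test_saturation_clamp(self):
        p = ef.PhotoreceptorParams(slope_m=4.0, i0=1e-3, v_max=10.0, fc=50.0)
        assert ef.steady_state_amplitude(p, 1e3, 0.0) == pytest.approx(10.0)

    def test_state_interpolation_is_monotone_in_sensitivity(self):
        light = DEFAULT_CONDITION_PARAMS[LA_DAY]
        dark = DEFAULT_CONDITION_PARAMS[DA_NIGHT]
        i0s = [ef.interpolate_params(light, dark, s).i0 for s in (0, 0.25, 0.5, 0.75, 1)]
        assert all(b < a for a, b in zip(i0s, i0s[1:]))
        assert i0s[0] == pytest.approx(light.i0, rel=1e-12)
        assert i0s[-1] == pytest.approx(dark.i0, rel=1e-12)

    def test_domain_errors(self):
        p = ef.PhotoreceptorParams(slope_m=4.0, i0=1e-3)
        with pytest.raises(DomainError):
            ef.steady_state_amplitude(p, -1.0)
        with pytest.raises(DomainError):
            ef.interpolate_params(p, p, 1.5)


class TestAcquisitionFilter:
    def test_100hz_attenuated_about_30_percent_vs_1hz(self):
        """First-order low-pass at 100 Hz: |H(100)| = 1/sqrt(2), a ~30% cut."""
        t = np.arange(int(FS * 21)) / FS
        amps = {}
        for f in (1.0, 100.0):
            x = np.sin(2 * np.pi * f * t)
            y = ef.acquisition_filter(x, FS, hp=0.0, lp=100.0)
            spec = ef.amplitude_spectrum(y[int(2 * FS):], FS)
            amps[f] = spec.amplitudes[spec.bin_index(f)]
        assert amps[100.0] / amps[1.0] == pytest.approx(0.707, abs=0.01)

    def test_sinusoid_gain_matches_analytic_magnitude(self):
        t = np.arange(int(FS * 21)) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        y = ef.acquisition_filter(x, FS, hp=1.0, lp=100.0)
        spec = ef.amplitude_spectrum(y[int(2 * FS):], FS)
        measured = spec.amplitudes[spec.bin_index(10.0)]
        assert measured == pytest.approx(ef.bandpass_gain(10.0), rel=0.02)
        assert ef.bandpass_gain(10.0) == pytest.approx(0.995 * 0.995, abs=0.002)

    def test_dc_offset_removed_by_highpass(self):
        y = ef.acquisition_filter(np.full(50_000, 5.0), FS, hp=1.0, lp=100.0)
        assert abs(np.mean(y[-5000:])) < 0.05

    def test_invalid_corner_order_rejected(self):
        with pytest.raises(ConfigError):
            ef.acquisition_filter(np.zeros(100), FS, hp=100.0, lp=1.0)


class TestSimulateRecording:
    def test_noise_free_fundamental_matches_requested_amplitude(self):
        p = DEFAULT_CONDITION_PARAMS[LA_DAY].quiet()
        stim = ef.StimulusSpec(on_intensity=30.0, frequency=10.0)
        rec = ef.simulate_recording(p, stim, seed=1)
        expected = ef.steady_state_amplitude(p, 30.0, 10.0)
        # acquisition chain costs ~1% at 10 Hz, inside the 2% band
        assert measured_fundamental(rec) == pytest.approx(expected, rel=0.02)

    def test_sub_threshold_stimulus_gives_noise_only(self):
        p = DEFAULT_CONDITION_PARAMS[LA_DAY]
        stim = ef.StimulusSpec(on_intensity=p.i0 / 100.0, frequency=10.0)
        rec = ef.simulate_recording(p, stim, seed=2)
        m = ef.measure_response(rec.samples, rec.fs, 10.0)
        assert m.amplitude < 5 * m.noise_mean

    def test_same_seed_reproduces_identically(self):
        p = DEFAULT_CONDITION_PARAMS[LA_NIGHT]
        stim = ef.StimulusSpec(on_intensity=1.0, frequency=10.0)
        a = ef.simulate_recording(p, stim, seed=3)
        b = ef.simulate_recording(p, stim, seed=3)
        assert np.array_equal(a.samples, b.samples)

    def test_fundamental_scales_linearly_with_response(self):
        p = DEFAULT_CONDITION_PARAMS[LA_DAY].quiet()
        stim = ef.StimulusSpec(on_intensity=30.0, frequency=10.0)
        base = measured_fundamental(ef.simulate_recording(p, stim, seed=1))
        # doubling the slope doubles the noise-free response and spectrum
        d = ef.simulate_recording(
            dataclasses.replace(p, slope_m=2 * p.slope_m), stim, seed=1
        )
        assert measured_fundamental(d) == pytest.approx(2 * base, rel=1e-6)

    def test_recording_metadata_carried(self):
        p = DEFAULT_CONDITION_PARAMS[LA_DAY]
        stim = ef.StimulusSpec(on_intensity=1.0, frequency=10.0)
        rec = ef.simulate_recording(
            p, stim, seed=5, crab_id="crab07", sex="M", condition=DA_NIGHT,
            probe_time=12.0,
        )
        assert rec.crab_id == "crab07" and rec.condition == DA_NIGHT
        assert rec.duration == pytest.approx(21.0)
        assert rec.samples.size == 105_000


class TestAdaptationState:
    def schedule(self, probes="all"):
        return build_dark_adaptation_protocol(probes=probes)

    def test_zero_gain_gives_monotone_trajectory(self):
        d = dataclasses.replace(DEFAULT_ADAPTATION_DYNAMICS, probe_light_adapt_gain=0.0)
        traj = ef.simulate_adaptation_state(d, self.schedule(), "night")
        assert np.all(np.diff(traj.s) >= -1e-12)

    def test_night_default_dips_between_12_and_24_minutes(self):
        traj = ef.simulate_adaptation_state(
            DEFAULT_ADAPTATION_DYNAMICS, self.schedule(), "night"
        )
        a = traj.probe_amplitudes
        t = traj.probe_times
        i = int(np.argmin(np.where((t > 12) & (t < 24), a, np.inf)))
        assert 12 < t[i] < 24
        assert a[i] < np.max(a[: i]) - 0.1  # genuine dip below the prior peak
        assert a[-1] > a[i]  # recovery afterwards

    def test_probing_costs_dark_adaptation(self):
        probed = ef.simulate_adaptation_state(
            DEFAULT_ADAPTATION_DYNAMICS, self.schedule(), "night"
        )
        control = ef.simulate_adaptation_state(
            DEFAULT_ADAPTATION_DYNAMICS, self.schedule("endpoints_only"), "night"
        )
        assert control.probe_states[-1] >= probed.probe_states[-1]

    def test_day_is_slower_and_shallower_than_night(self):
        day = ef.simulate_adaptation_state(
            DEFAULT_ADAPTATION_DYNAMICS, self.schedule(), "day"
        )
        night = ef.simulate_adaptation_state(
            DEFAULT_ADAPTATION_DYNAMICS, self.schedule(), "night"
        )
        assert night.probe_amplitudes[-1] > day.probe_amplitudes[-1]
        assert night.s[night.t_min <= 12].max() > day.s[day.t_min <= 12].max()


class TestCohorts:
    def test_exp1_recording_count(self):
        ds = ef.simulate_cohort_exp1(ef.CohortConfig(n_crabs=2), seed=0, n_intensities=5)
        assert len(ds) == 2 * 4 * 5
        assert len(ds.truth) == 8

    def test_zero_between_crab_variance_makes_crabs_identical(self, quiet_params):
        cfg = ef.CohortConfig(
            n_crabs=2, condition_params=quiet_params,
            between_crab_sd_log_i0=0.0, between_crab_sd_slope=0.0,
            sex_amplitude_effect=0.0,
        )
        ds = ef.simulate_cohort_exp1(cfg, seed=0, n_intensities=3,
                                     conditions=[LA_DAY])
        a = [r for r in ds.recordings if r.crab_id == "crab01"]
        b = [r for r in ds.recordings if r.crab_id == "crab02"]
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.samples, rb.samples)

    def test_missing_condition_params_rejected(self):
        with pytest.raises(ConfigError):
            ef.CohortConfig(condition_params={LA_DAY: DEFAULT_CONDITION_PARAMS[LA_DAY]})

    def test_sex_effect_recovers_in_fitted_amplitudes(self, quiet_params):
        """Female recordings carry an extra ~delta µV of response."""
        delta = 1.5
        cfg = ef.CohortConfig(
            n_crabs=4, condition_params=quiet_params,
            between_crab_sd_log_i0=0.0, between_crab_sd_slope=0.0,
            sex_amplitude_effect=delta,
        )
        ds = ef.simulate_cohort_exp1(cfg, seed=1, n_intensities=4,
                                     start_rel_log10=0.5, conditions=[LA_DAY])
        meas = ef.measure_dataset(ds, preprocess=False)
        by_sex = meas.groupby("sex")["amplitude"].mean()
        assert by_sex["F"] - by_sex["M"] == pytest.approx(delta, rel=0.1)

    def test_exp2_uses_individually_normalised_intensities(self, quiet_params):
        cfg = ef.CohortConfig(n_crabs=1, condition_params=quiet_params,
                              between_crab_sd_log_i0=0.0,
                              between_crab_sd_slope=0.0,
                              sex_amplitude_effect=0.0)
        ds = ef.simulate_cohort_exp2(cfg, seed=0, conditions=[LA_DAY])
        rec10 = next(r for r in ds.recordings if r.stimulus.frequency == 10.0)
        assert measured_fundamental(rec10) == pytest.approx(3.2, rel=0.02)

    def test_exp3_control_runs_have_two_probes(self):
        ds = ef.simulate_cohort_exp3(ef.CohortConfig(n_crabs=1), seed=0)
        ctrl = ds.meta[ds.meta["probes"] == "endpoints_only"]
        assert ctrl.groupby("time_of_day").size().eq(2).all()
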