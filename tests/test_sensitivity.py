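import numpy as np
import pytest

import ergflick as ef
from ergflick.errors import EstimationError, FitError
from ergflick.spectral import ResponseMeasure


def rm(amplitude, significant=True, noise_mean=0.0):
    return ResponseMeasure(
        amplitude=amplitude, noise_mean=noise_mean, noise_max=noise_mean,
        noise_min=0.0, alpha=0.0 if significant else 0.5,
        significant=significant, n_noise_bins=40, stim_freq=10.0,
        frequency_resolution=1 / 21.0,
    )


def line_points(slope=4.0, intercept=12.0, logs=(-3.5, -3.0, -2.5, -2.0, -1.5, -1.0)):
    return [(10.0**x, rm(slope * x + intercept)) for x in logs]


class TestVlogIFit:
    def test_exact_line_recovered(self):
        curve = ef.fit_v_logI(line_points())
        assert curve.slope == pytest.approx(4.0, abs=1e-9)
        assert curve.intercept == pytest.approx(12.0, abs=1e-9)
        assert curve.r2 == pytest.approx(1.0, abs=1e-12)

    def test_saturated_points_excluded_by_guard(self):
        pts = line_points(logs=(-2.5, -2.0, -1.5, -1.0))
        pts += [(10.0**-0.5, rm(10.0)), (10.0**0.0, rm(10.0))]
        curve = ef.fit_v_logI(pts)
        assert curve.slope == pytest.approx(4.0, abs=1e-9)
        assert all(i < 4 for i in curve.fit_points)

    def test_all_non_significant_is_a_fit_error(self):
        pts = [(i, rm(0.01, significant=False)) for i in (1e-4, 1e-3, 1e-2)]
        with pytest.raises(FitError):
            ef.fit_v_logI(pts)

    def test_isolated_false_positive_below_threshold_is_dropped(self):
        """A spuriously significant noise point far below the response run
        must not lever the fitted slope."""
        pts = [(10.0**-6.0, rm(0.03, noise_mean=0.01))]
        pts += [(10.0**x, rm(0.01, significant=False)) for x in (-5.5, -5.0)]
        pts += line_points(logs=(-2.5, -2.0, -1.5, -1.0))
        curve = ef.fit_v_logI(pts)
        assert 0 not in curve.fit_points
        assert curve.slope == pytest.approx(4.0, abs=1e-9)


class TestThresholdInterpolation:
    def curve(self):
        return ef.fit_v_logI(line_points())

    def test_one_microvolt_inversion(self):
        est = ef.intensity_at_amplitude(self.curve(), 1.0)
        assert est.intensity == pytest.approx(10**-2.75, rel=1e-9)

    def test_criterion_equal_to_intercept(self):
        est = ef.intensity_at_amplitude(self.curve(), 12.0)
        assert est.intensity == pytest.approx(1.0, rel=1e-9)
        assert est.extrapolated  # log10 I = 0 sits above the fitted range

    def test_three_point_two_microvolt_inversion(self):
        est = ef.intensity_at_amplitude(self.curve(), 3.2)
        assert est.intensity == pytest.approx(10**-2.2, rel=1e-9)
        assert not est.extrapolated

    def test_non_positive_slope_rejected(self):
        bad = ef.VlogICurve(slope=-1.0, intercept=0.0, fit_points=(0, 1),
                            r2=1.0, log10_i_range=(-3, -1))
        with pytest.raises(EstimationError):
            ef.intensity_at_amplitude(bad, 1.0)


class TestFFF:
    def test_linear_interpolation_between_bracketing_frequencies(self):
        pts = [(10.0, rm(3.0)), (20.0, rm(2.0)), (30.0, rm(1.0)), (40.0, rm(0.4))]
        est = ef.estimate_fff(pts, 0.6)
        assert est.fff == pytest.approx(30 + 10 * (1 - 0.6) / (1 - 0.4), rel=1e-9)
        assert est.bracket == (30.0, 40.0)

    def test_all_above_criterion_flagged_above_range(self):
        pts = [(f, rm(2.0)) for f in (10.0, 60.0, 120.0)]
        est = ef.estimate_fff(pts, 0.6)
        assert est.flag == "above_range" and est.fff == 120.0

    def test_all_below_criterion_flagged_below_range(self):
        pts = [(f, rm(0.1)) for f in (10.0, 20.0, 30.0)]
        est = ef.estimate_fff(pts, 0.6)
        assert est.flag == "below_range" and est.fff == 10.0

    def test_crossing_exactly_at_a_tested_frequency(self):
        pts = [(40.0, rm(1.2)), (50.0, rm(0.9)), (60.0, rm(0.6)), (70.0, rm(0.3))]
        est = ef.estimate_fff(pts, 0.6, exclude=())
        assert est.fff == 60.0

    def test_excluded_mains_frequency_never_used(self):
        pts = [(40.0, rm(1.0)), (50.0, rm(5.0)), (60.0, rm(0.5)), (70.0, rm(0.2))]
        est = ef.estimate_fff(pts, 0.6, exclude=(50.0,))
        # with 50 Hz gone the crossing is between 40 and 60
        assert est.bracket == (40.0, 60.0)
        assert 40 < est.fff < 60

    def test_non_significant_high_frequency_points_do_not_count(self):
        pts = [(10.0, rm(2.0)), (20.0, rm(1.0)),
               (30.0, rm(0.7, significant=False)), (40.0, rm(0.1))]
        est = ef.estimate_fff(pts, 0.6)
        assert est.bracket == (20.0, 30.0)

    def test_increasing_corner_frequency_raises_fff(self, quiet_params):
        """On noiseless recordings the estimated fusion point moves up
        monotonically with the simulator's temporal corner."""
        import dataclasses
        from ergflick.synthetic_data import LA_DAY

        base = quiet_params[LA_DAY]
        est = []
        for fc in (15.0, 25.0, 40.0):
            p = dataclasses.replace(base, fc=fc)
            intensity = ef.intensity_for_amplitude(p, 3.2)
            series = ef.build_exp2_series(intensity)
            pts = []
            for stim in series.stimuli:
                rec = ef.simulate_recording(p, stim, seed=0)
                pts.append(
                    (stim.frequency,
                     ef.measure_response(rec.samples, rec.fs, stim.frequency))
                )
            est.append(ef.estimate_fff(pts, 0.6).fff)
        assert est[0] < est[1] < est[2]


class TestAdaptationFeatures:
    def test_linear_rise_has_slope_and_no_dip(self):
        t = np.arange(0.0, 64.0, 4.0)
        a = 0.1 * t
        f = ef.adaptation_features(t, a)
        assert f.initial_slope == pytest.approx(0.1, rel=1e-9)
        assert f.dip_depth == 0.0
        assert f.final_amp == pytest.approx(6.0)

    def test_constant_amplitude_all_features_flat(self):
        t = np.arange(0.0, 64.0, 4.0)
        f = ef.adaptation_features(t, np.full(t.size, 2.5))
        assert f.initial_slope == pytest.approx(0.0, abs=1e-12)
        assert f.dip_depth == 0.0
        assert f.final_amp == 2.5 and f.mean_12_24 == 2.5

    def test_built_in_dip_is_located(self):
        t = np.arange(0.0, 64.0, 4.0)
        a = np.minimum(0.5 * t, 8.0)
        a[(t >= 16) & (t <= 24)] -= 3.0  # carve a dip
        # running max just before the dip is a(12) = 6, dip floor is 5
        f = ef.adaptation_features(t, a)
        assert f.dip_time == 16.0
        assert f.dip_depth == pytest.approx(1.0)

    def test_too_few_probes_rejected(self):
        with pytest.raises(EstimationError):
            ef.adaptation_features([0.0, 60.0], [1.0, 2.0])


class TestThresholdRecoveryProperty:
    def test_recovered_thresholds_match_ground_truth(self, exp1_cohort_measures):
        """Pipeline-recovered 1 µV criterion intensities agree with the
        generator's configured truth within 0.1 log10 units, per crab and
        condition, on a default-noise cohort."""
        ds, measures = exp1_cohort_measures
        thr = ef.thresholds_from_measures(measures)
        merged = thr.merge(ds.truth, on=["crab_id", "condition"])
        err = merged["log10_threshold"] - np.log10(merged["true_threshold_1uv"])
        assert len(merged) == 32
        assert err.abs().max() < 0.1

    def test_normalisation_consistency(self, quiet_params):
        """Stimulating at the fitted 3.2 µV intensity returns ~3.2 µV."""
        import dataclasses
        from ergflick.synthetic_data import LA_NIGHT

        p = dataclasses.replace(quiet_params[LA_NIGHT], noise_sd=2.0)
        series = ef.build_intensity_series(p.i0 / 30, 1 / 3, 15)
        pts = []
        rng = np.random.default_rng(5)
        for stim in series.stimuli:
            rec = ef.simulate_recording(p, stim, rng)
            pp = ef.preprocess_trace(rec.samples, rec.fs)
            pts.append((stim.on_intensity,
                        ef.measure_response(pp.trace, rec.fs, 10.0)))
        curve = ef.fit_v_logI(pts)
        est = ef.intensity_at_amplitude(curve, 3.2)
        rec = ef.simulate_recording(
            p, ef.StimulusSpec(on_intensity=est.intensity, frequency=10.0), rng
        )
        pp = ef.preprocess_trace(rec.samples, rec.fs)
        m = ef.measure_response(pp.trace, rec.fs, 10.0)
        assert m.amplitude == pytest.approx(3.2, rel=0.15)
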