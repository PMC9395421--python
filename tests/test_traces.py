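import numpy as np
import pytest

import photocyt as pc
from photocyt.errors import AlignmentError, ConfigError, ProtocolError
from photocyt.traces import ConcentrationSeries


def staircase_trace(levels=(0.0, 1.0, 1.8, 2.4), rc_uM=1.0):
    """Ideal noiseless staircase on the standard three-flash protocol."""
    protocol = pc.default_flash_protocol()
    n = int(round(protocol.duration / protocol.sampling_dt))
    time = np.arange(n + 1) * protocol.sampling_dt
    per_rc = np.zeros_like(time)
    for lvl, t_f in zip(levels[1:], protocol.flash_times):
        per_rc[time > t_f] = lvl
    delta_a = -21.1 * 1.0 * per_rc * rc_uM * 1e-3
    return pc.AbsorbanceTrace(time=time, delta_a=delta_a, rc_conc_uM=rc_uM,
                              protocol=protocol), protocol


class TestBeerLambert:
    def test_zero_absorbance_zero_concentration(self):
        tr, _ = staircase_trace(levels=(0, 0, 0, 0))
        conc = pc.absorbance_to_concentration(tr)
        np.testing.assert_array_equal(conc.conc_uM, 0.0)

    def test_known_conversion(self):
        """dA = -0.0211 at de = 21.1 mM^-1 cm^-1, l = 1 cm -> 1.0 uM."""
        time = np.arange(10) * 50e-6
        tr = pc.AbsorbanceTrace(time=time, delta_a=np.full(10, -0.0211))
        conc = pc.absorbance_to_concentration(tr)
        np.testing.assert_allclose(conc.conc_uM, 1.0)
        tr2 = pc.AbsorbanceTrace(time=time, delta_a=np.full(10, -0.0211),
                                 rc_conc_uM=0.5)
        conc2 = pc.absorbance_to_concentration(tr2)
        np.testing.assert_allclose(conc2.per_rc, 2.0)

    def test_missing_coefficient_is_config_error(self):
        tr = pc.AbsorbanceTrace(time=np.arange(5) * 50e-6, delta_a=np.zeros(5),
                                wavelength_pair="600-650")
        assert tr.delta_epsilon is None
        with pytest.raises(ConfigError):
            pc.absorbance_to_concentration(tr)

    def test_oxidation_positive_on_both_wavelength_pairs(self):
        """Negative-going dA at 551-540 and 790-750 both report positive
        oxidized concentrations on synthetic traces."""
        preset = pc.strain_preset("rba_cycA")  # P+ persists: clean P+ signal
        for observable in ("cyt", "pplus"):
            trace, _ = pc.generate_flash_experiment(
                pc.strain_preset("rvx_wt") if observable == "cyt" else preset,
                noise=pc.NoiseModel(sigma_delta_a=0.0),
                observable=observable)
            conc = pc.absorbance_to_concentration(trace)
            assert conc.conc_uM.min() >= -1e-12
            assert conc.conc_uM.max() > 0.1


class TestExtractSteps:
    def test_ideal_staircase_differences(self):
        tr, protocol = staircase_trace()
        conc = pc.absorbance_to_concentration(tr)
        steps = pc.extract_steps(conc, protocol)
        assert steps.as_tuple() == pytest.approx((1.0, 0.8, 0.6))

    def test_no_flashes_is_error(self):
        tr, _ = staircase_trace()
        conc = pc.absorbance_to_concentration(tr)
        empty = pc.IlluminationProtocol(mode="flash_train", duration=2e-3)
        with pytest.raises(ProtocolError):
            pc.extract_steps(conc, empty)

    def test_window_overlapping_next_flash_is_error(self):
        tr, protocol = staircase_trace()
        conc = pc.absorbance_to_concentration(tr)
        with pytest.raises(ProtocolError):
            pc.extract_steps(conc, protocol, window=(100e-6, 450e-6))

    def test_recovers_generator_ground_truth_within_noise(self):
        noise = pc.NoiseModel(sigma_delta_a=1e-3, n_averages=32, seed=11)
        trace, truth = pc.generate_flash_experiment(pc.strain_preset("rvx_wt"),
                                                    noise=noise)
        conc = pc.absorbance_to_concentration(trace)
        steps = pc.extract_steps(conc, trace.protocol)
        # plateau mean over ~6 samples at effective sigma/(de l [RC])
        sigma_step = np.sqrt(2 / 6) * noise.effective_sigma / (21.1e-3 * 1.0)
        for measured, true in zip(steps.as_tuple(),
                                  pc.StepHeights.from_dict(truth["steps_true"]).as_tuple()):
            assert abs(measured - true) < 3 * sigma_step


class TestFitThreePhases:
    def design(self, slopes=(1.5e4, 3.0e3, 50.0), breaks=(1e-3, 1e-2),
               duration=20e-3, dt=50e-6):
        t = np.arange(int(round(duration / dt)) + 1) * dt
        y = slopes[0] * np.minimum(t, breaks[0])
        y += slopes[1] * np.clip(np.minimum(t, breaks[1]) - breaks[0], 0, None)
        y += slopes[2] * np.clip(t - breaks[1], 0, None)
        return ConcentrationSeries(time=t, conc_uM=y, per_rc=y)

    def test_exact_recovery_on_exact_input(self):
        fit = pc.fit_three_phases(self.design())
        assert fit.slopes == pytest.approx((1.5e4, 3.0e3, 50.0), rel=1e-6)
        assert fit.breakpoints == pytest.approx((1e-3, 1e-2), rel=1e-9)
        assert not fit.diagnostics.get("degenerate", False)

    def test_single_line_reports_one_slope_thrice_with_warning(self):
        t = np.arange(200) * 50e-6
        fit = pc.fit_three_phases(ConcentrationSeries(t, 100.0 * t))
        assert fit.slopes == pytest.approx((100.0, 100.0, 100.0), abs=1e-6)
        assert fit.diagnostics["degenerate"] is True

    def test_scale_equivariance(self):
        base = self.design()
        scaled = ConcentrationSeries(base.time, 3.5 * base.conc_uM,
                                     3.5 * base.per_rc)
        f1 = pc.fit_three_phases(base)
        f2 = pc.fit_three_phases(scaled)
        np.testing.assert_allclose(np.array(f2.slopes), 3.5 * np.array(f1.slopes),
                                   rtol=1e-9)
        assert f1.breakpoints == f2.breakpoints

    def test_too_short_trace_rejected(self):
        t = np.arange(10) * 50e-6
        with pytest.raises(ValueError):
            pc.fit_three_phases(ConcentrationSeries(t, t))


class TestAverageTraces:
    def test_single_trace_is_identity(self):
        tr, _ = staircase_trace()
        out = pc.average_traces([tr])
        np.testing.assert_array_equal(out.delta_a, tr.delta_a)
        assert out.n_averages == tr.n_averages

    def test_noise_reduction_scales_as_sqrt_n(self, rng):
        # long flat trace so the SD estimator itself is well determined
        time = np.arange(801) * 50e-6
        tr = pc.AbsorbanceTrace(time=time, delta_a=np.full(801, -0.01))
        sigma = 1e-3
        copies = []
        for _ in range(32):
            noisy = tr.delta_a + rng.normal(0, sigma, tr.delta_a.shape)
            copies.append(pc.AbsorbanceTrace(time=tr.time, delta_a=noisy,
                                             protocol=tr.protocol,
                                             rc_conc_uM=tr.rc_conc_uM))
        avg = pc.average_traces(copies)
        resid_sd = np.std(avg.delta_a - tr.delta_a)
        assert resid_sd == pytest.approx(sigma / np.sqrt(32), rel=0.15)
        assert avg.n_averages == 32

    def test_mismatched_grids_rejected(self):
        tr, _ = staircase_trace()
        short = pc.AbsorbanceTrace(time=tr.time[:-5], delta_a=tr.delta_a[:-5],
                                   protocol=None)
        with pytest.raises(AlignmentError):
            pc.average_traces([tr, short])


class TestNormalizeToReference:
    def test_series_equal_to_reference_maps_to_unity(self):
        t = np.arange(20) * 50e-6
        series = ConcentrationSeries(t, np.full(20, 0.7))
        out = pc.normalize_to_reference(series, 0.7)
        np.testing.assert_allclose(out.per_rc, 1.0)

    def test_nonpositive_reference_rejected(self):
        series = ConcentrationSeries(np.arange(5.0), np.ones(5))
        with pytest.raises(ValueError):
            pc.normalize_to_reference(series, 0.0)

    def test_cyca_pplus_single_flash_calibrates_per_rc(self):
        """The cytochrome-less strain's single-flash P+ amplitude is the
        1/RC internal standard: normalizing a wild-type staircase by it
        reproduces the simulated per-RC steps."""
        protocol = pc.default_flash_protocol(n_flashes=1)
        ref_trace, _ = pc.generate_flash_experiment(
            pc.strain_preset("rba_cycA"), protocol,
            pc.NoiseModel(sigma_delta_a=0.0), observable="pplus")
        ref_conc = pc.absorbance_to_concentration(ref_trace)
        ref_amplitude = float(np.max(ref_conc.conc_uM))
        assert ref_amplitude == pytest.approx(1.0, rel=1e-6)  # [RC] = 1 uM

        wt_trace, truth = pc.generate_flash_experiment(
            pc.strain_preset("rvx_wt"), noise=pc.NoiseModel(sigma_delta_a=0.0))
        wt_conc = pc.absorbance_to_concentration(wt_trace)
        normalized = pc.normalize_to_reference(
            ConcentrationSeries(wt_conc.time, wt_conc.conc_uM), ref_amplitude)
        steps = pc.extract_steps(normalized, wt_trace.protocol)
        true_steps = pc.StepHeights.from_dict(truth["steps_true"])
        assert steps.as_tuple() == pytest.approx(true_steps.as_tuple(), abs=1e-6)


class TestTraceContainer:
    def test_nonuniform_grid_rejected(self):
        t = np.array([0.0, 1e-5, 3e-5, 6e-5])
        with pytest.raises(ValueError):
            pc.AbsorbanceTrace(time=t, delta_a=np.zeros(4))

    def test_csv_round_trip_preserves_data_and_metadata(self, tmp_path):
        trace, _ = pc.generate_flash_experiment(pc.strain_preset("rba_wt"),
                                                noise=pc.NoiseModel(seed=5))
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        back = pc.AbsorbanceTrace.from_csv(path)
        np.testing.assert_allclose(back.delta_a, trace.delta_a)
        np.testing.assert_allclose(back.time, trace.time)
        assert back.wavelength_pair == trace.wavelength_pair
        assert back.delta_epsilon == trace.delta_epsilon
        assert back.n_averages == trace.n_averages
        assert back.protocol.flash_times == trace.protocol.flash_times
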