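import numpy as np
import pytest

import photocyt as pc
from photocyt.synthetic import calibrate_donor_links


class TestStrainPresets:
    def test_unknown_names_listed_in_error(self):
        with pytest.raises(LookupError, match="rvx_wt"):
            pc.strain_preset("nonexistent")
        with pytest.raises(LookupError):
            pc.strain_preset("rvx_wt", "unknown-treatment")

    def test_rvx_wild_type_acceptor_rates(self):
        """Whole-cell interquinone rates: 1e4 and 7.2e3 s^-1 for Rvx."""
        p = pc.strain_preset("rvx_wt")
        assert p.rates.k_AB1 == 1.0e4
        assert p.rates.k_AB2 == 7.2e3
        assert pc.strain_preset("rba_wt").rates.k_AB1 == 1.2e4
        assert pc.strain_preset("rba_wt").rates.k_AB2 == 6.0e3

    def test_terbutryne_zeroes_interquinone_transfer_only(self):
        p = pc.strain_preset("rvx_wt", "terbutryne")
        base = pc.strain_preset("rvx_wt")
        assert p.rates.k_AB1_eff == 0.0 and p.rates.k_AB2_eff == 0.0
        assert p.rates.k_ET == base.rates.k_ET
        assert p.rates.N_pool == base.rates.N_pool

    def test_cyca_has_no_donor_cytochromes(self):
        p = pc.strain_preset("rba_cycA")
        assert p.rates.N_pool == 0.0
        assert p.implied_kd is None
        sim = pc.simulate_flash_train(p.rates, pc.default_flash_protocol())
        np.testing.assert_allclose(sim.flash_increments, 0.0, atol=1e-12)
        assert sim.pplus_per_rc[-1] == pytest.approx(1.0, abs=1e-6)

    def test_myxothiazol_slows_pool_resupply(self):
        p = pc.strain_preset("rvx_wt", "myxothiazol")
        assert p.rates.k_bc1_eff == pytest.approx(10.0)   # (100 ms)^-1
        assert pc.strain_preset("rvx_wt").rates.k_bc1_eff == pytest.approx(100.0)

    def test_calibration_reproduces_targets_noiselessly(self):
        """Back-solved link constants make the noiseless pipeline return the
        preset's damping constants to the calibration tolerance."""
        for name, (kd2, kd3) in (("rvx_wt", (49.0, 3.7)),
                                 ("rba_wt", (3.5, 1.4)),
                                 ("rvx_pufC", (0.75, 0.3))):
            preset = pc.strain_preset(name)
            trace, truth = pc.generate_flash_experiment(
                preset, noise=pc.NoiseModel(sigma_delta_a=0.0))
            assert truth["kd_true"]["kd2"] == pytest.approx(kd2, rel=1e-3)
            assert truth["kd_true"]["kd3"] == pytest.approx(kd3, rel=1e-3)

    def test_calibrated_links_are_non_increasing(self):
        for name in ("rvx_wt", "rba_wt", "rvx_pufC"):
            k1, k2, k3 = calibrate_donor_links(name)
            assert k1 >= k2 >= k3 > 0


class TestFlashExperiments:
    def test_noiseless_trace_is_exact_staircase(self):
        preset = pc.strain_preset("rba_wt")
        trace, _ = pc.generate_flash_experiment(
            preset, noise=pc.NoiseModel(sigma_delta_a=0.0))
        sim = pc.simulate_flash_train(preset.rates, trace.protocol)
        expected = -21.1 * 1.0 * sim.cyt3_per_rc * 1.0 * 1e-3
        np.testing.assert_allclose(trace.delta_a, expected, atol=1e-15)

    def test_seeded_runs_are_bit_identical(self, tmp_path):
        preset = pc.strain_preset("rvx_wt")
        t1, truth1 = pc.generate_flash_experiment(preset, noise=pc.NoiseModel(seed=42))
        t2, truth2 = pc.generate_flash_experiment(preset, noise=pc.NoiseModel(seed=42))
        np.testing.assert_array_equal(t1.delta_a, t2.delta_a)
        assert truth1 == truth2
        t1.to_csv(tmp_path / "a.csv")
        t2.to_csv(tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_different_seeds_differ(self):
        preset = pc.strain_preset("rvx_wt")
        t1, _ = pc.generate_flash_experiment(preset, noise=pc.NoiseModel(seed=1))
        t2, _ = pc.generate_flash_experiment(preset, noise=pc.NoiseModel(seed=2))
        assert not np.array_equal(t1.delta_a, t2.delta_a)

    def test_noise_scales_as_inverse_sqrt_averages(self):
        # long continuous trace (401 samples) for a stable SD estimate
        preset = pc.strain_preset("rvx_wt")
        clean, _ = pc.generate_continuous_experiment(
            preset, noise=pc.NoiseModel(sigma_delta_a=0.0))
        sds = {}
        for n in (1, 8, 32):
            noisy, _ = pc.generate_continuous_experiment(
                preset, noise=pc.NoiseModel(sigma_delta_a=1e-3, n_averages=n,
                                            seed=99))
            sds[n] = np.std(noisy.delta_a - clean.delta_a)
        for n in (1, 8, 32):
            assert sds[n] == pytest.approx(1e-3 / np.sqrt(n), rel=0.15)

    def test_end_to_end_kd_recovery_within_ten_percent(self):
        """Full pipeline at default noise recovers each preset's constants."""
        for name, kd2, kd3 in (("rvx_wt", 49.0, 3.7), ("rba_wt", 3.5, 1.4),
                               ("rvx_pufC", 0.75, 0.3)):
            trace, _ = pc.generate_flash_experiment(
                pc.strain_preset(name), noise=pc.NoiseModel(seed=2024))
            conc = pc.absorbance_to_concentration(trace)
            steps = pc.extract_steps(conc, trace.protocol)
            kd = pc.invert_steps(steps, clip_tol=0.01)
            assert kd.kd2 == pytest.approx(kd2, rel=0.10)
            assert kd.kd3 == pytest.approx(kd3, rel=0.10)


class TestContinuousExperiments:
    def test_no_light_flat_noise_around_zero(self):
        trace, _ = pc.generate_continuous_experiment(
            pc.strain_preset("rvx_wt"), k_L=0.0,
            noise=pc.NoiseModel(sigma_delta_a=1e-3, seed=3), mode="mechanistic")
        assert abs(np.mean(trace.delta_a)) < 3 * 1e-3 / np.sqrt(32 * trace.time.size)

    def test_designed_mode_matches_declared_ground_truth(self):
        trace, truth = pc.generate_continuous_experiment(
            pc.strain_preset("rvx_wt"), noise=pc.NoiseModel(sigma_delta_a=0.0))
        assert truth["mode"] == "designed"
        assert truth["slopes"][0] == 1.5e4
        conc = pc.absorbance_to_concentration(trace)
        fit = pc.fit_three_phases(conc)
        assert fit.slopes == pytest.approx(tuple(truth["slopes"]), rel=1e-6)

    def test_terbutryne_saturates_at_single_turnover(self):
        trace, truth = pc.generate_continuous_experiment(
            pc.strain_preset("rvx_wt", "terbutryne"),
            noise=pc.NoiseModel(sigma_delta_a=0.0))
        assert truth["mode"] == "mechanistic"
        conc = pc.absorbance_to_concentration(trace)
        assert conc.per_rc[-1] == pytest.approx(1.0, rel=0.02)
        assert np.all(np.diff(conc.per_rc) > -1e-9)

    def test_duration_must_cover_design(self):
        from photocyt.errors import ProtocolError
        with pytest.raises(ProtocolError):
            pc.generate_continuous_experiment(pc.strain_preset("rvx_wt"),
                                              duration=5e-3)


class TestFerricyanideTitration:
    def test_zero_incubation_matches_untreated_preset(self):
        preset = pc.strain_preset("rvx_wt")
        exps, _ = pc.generate_ferricyanide_titration(
            preset, [0.0], noise=pc.NoiseModel(sigma_delta_a=0.0))
        t0, trace0 = exps[0]
        untreated, _ = pc.generate_flash_experiment(
            preset, noise=pc.NoiseModel(sigma_delta_a=0.0))
        assert t0 == 0.0
        np.testing.assert_allclose(trace0.delta_a, untreated.delta_a, atol=1e-12)

    def test_recovered_constants_decline_monotonically(self):
        preset = pc.strain_preset("rvx_wt")
        _, truth = pc.generate_ferricyanide_titration(
            preset, [0.0, 1800.0, 3600.0, 7200.0],
            noise=pc.NoiseModel(sigma_delta_a=0.0))
        for key in ("kd1", "kd2", "kd3"):
            vals = [el["kd_true"][key] for el in truth["series"]]
            assert all(a > b for a, b in zip(vals, vals[1:])), (key, vals)

    def test_long_incubation_kills_the_steps(self):
        preset = pc.strain_preset("rvx_wt")
        exps, truth = pc.generate_ferricyanide_titration(
            preset, [8 * 3600.0], noise=pc.NoiseModel(sigma_delta_a=0.0))
        steps = truth["series"][0]["steps_true"]
        assert steps["delta1"] < 0.05

    def test_negative_oxidation_rate_rejected(self):
        with pytest.raises(ValueError):
            pc.generate_ferricyanide_titration(pc.strain_preset("rvx_wt"),
                                               [0.0], k_ox=-1.0)
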