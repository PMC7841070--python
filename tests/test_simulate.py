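from dataclasses import replace

import numpy as np
import pytest

from itcfit import (
    IndeterminateParametersError,
    OneSiteBindingModel,
    integrate_peaks,
    micellar_recipe,
    monomer_control_recipe,
    predicted_heats,
    simulate_power_trace,
    simulate_titration,
    subtract_blank,
)


class TestSimulateTitration:
    def test_noiseless_without_dilution_equals_forward_model(self, schedule):
        rec = micellar_recipe(5.1, 2.41, noise_fraction=0.0, blank_fraction=0.0)
        gross, blank = simulate_titration(rec)
        np.testing.assert_allclose(
            gross.heats, predicted_heats(schedule, rec.binding), rtol=1e-12)
        np.testing.assert_array_equal(blank.heats, 0.0)

    def test_seed_reproducibility(self):
        rec = micellar_recipe(5.1, 2.41, seed=42)
        g1, b1 = simulate_titration(rec)
        g2, b2 = simulate_titration(rec)
        np.testing.assert_array_equal(g1.heats, g2.heats)
        np.testing.assert_array_equal(b1.heats, b2.heats)
        g3, _ = simulate_titration(replace(rec, seed=43))
        assert np.any(g3.heats != g1.heats)

    def test_blank_is_linear_in_injected_moles(self, schedule):
        rec = micellar_recipe(5.1, 2.41, noise_fraction=0.0)
        _, blank = simulate_titration(rec)
        moles = np.asarray(schedule.injection_volumes) * schedule.syringe_guest_molar
        np.testing.assert_allclose(blank.heats,
                                   rec.dilution_coefficient * moles, rtol=1e-12)

    def test_end_to_end_recovery_within_three_sd(self):
        rec = micellar_recipe(5.1, 2.41, seed=42)
        g, b = simulate_titration(rec)
        res = OneSiteBindingModel([(rec.schedule, subtract_blank(g, b).net)]).fit()
        assert abs(res.params.log_k - 5.1) < 3 * res.bse[0]
        assert abs(res.params.delta_h - 2.41) < 3 * res.bse[1]

    def test_exothermic_endothermic_sign_dichotomy(self):
        """ΔH < 0 recipes evolve positive heat, ΔH > 0 negative — the
        chloramphenicol vs ofloxacin/tetracycline pattern."""
        for log_k, dh in [(2.6, -21.35), (2.6, -18.55)]:
            rec = micellar_recipe(log_k, dh, noise_fraction=0.0, blank_fraction=0.0)
            gross, _ = simulate_titration(rec)
            assert np.all(gross.heats > 0)
        for log_k, dh in [(5.1, 2.41), (2.5, 23.5), (2.6, 19.2), (5.1, 2.31)]:
            rec = micellar_recipe(log_k, dh, noise_fraction=0.0, blank_fraction=0.0)
            gross, _ = simulate_titration(rec)
            assert np.all(gross.heats < 0)


class TestMonomerControl:
    def test_binding_heats_below_noise_floor(self):
        """At 2.5 µM host the predicted binding heats fall below the
        0.5 µJ noise floor; ≥95% of net heats lie within three times the
        net-heat noise (blank subtraction carries √2 · noise_sd)."""
        rec = monomer_control_recipe(seed=0)
        assert np.max(np.abs(predicted_heats(rec.schedule, rec.binding))) < rec.noise_sd
        sd_net = np.sqrt(2.0) * rec.noise_sd
        frac = []
        for s in range(20):
            g, b = simulate_titration(monomer_control_recipe(seed=s))
            net = subtract_blank(g, b).net
            frac.append(np.mean(np.abs(net) < 3 * sd_net))
        assert np.mean(frac) >= 0.95

    def test_fitter_mostly_reports_indeterminate(self):
        indet = 0
        n = 40
        for s in range(n):
            rec = monomer_control_recipe(seed=s)
            g, b = simulate_titration(rec)
            m = OneSiteBindingModel([(rec.schedule, subtract_blank(g, b).net)])
            try:
                m.fit()
            except IndeterminateParametersError:
                indet += 1
        assert indet > n // 2


class TestSimulatePowerTrace:
    def test_zero_heats_give_flat_trace(self, schedule):
        rec = micellar_recipe(5.1, 2.41)
        tr = simulate_power_trace(np.zeros(25), schedule, rec)
        np.testing.assert_allclose(tr.power, 0.0, atol=1e-30)

    def test_round_trip_recovers_heats(self, schedule):
        rec = micellar_recipe(5.1, 2.41, seed=1)
        gross, _ = simulate_titration(rec)
        tr = simulate_power_trace(gross.heats, schedule, rec)
        recovered = integrate_peaks(tr)
        scale = np.max(np.abs(gross.heats))
        np.testing.assert_allclose(recovered, gross.heats, atol=0.01 * scale)

    def test_baseline_drift_robustness(self, schedule):
        rec = micellar_recipe(5.1, 2.41, seed=1)
        gross, _ = simulate_titration(rec)
        tr = simulate_power_trace(gross.heats, schedule,
                                  replace(rec, baseline_drift_w=0.1e-6))
        recovered = integrate_peaks(tr)
        scale = np.max(np.abs(gross.heats))
        np.testing.assert_allclose(recovered, gross.heats, atol=0.01 * scale)

    def test_pulse_overlap_rejected(self, schedule):
        rec = micellar_recipe(5.1, 2.41)
        with pytest.raises(ValueError):
            simulate_power_trace(np.ones(25) * 1e-6, schedule,
                                 replace(rec, response_sigma_s=60.0))


class TestFullPipelinePublishedRows:
    @pytest.mark.parametrize("log_k, delta_h", [
        (5.1, 2.41), (2.5, 23.5), (2.6, -21.35),
        (5.1, 2.31), (2.6, 19.2), (2.6, -18.55),
    ])
    def test_trace_to_signature_recovery(self, log_k, delta_h):
        """trace → integrate → blank-subtract → fit → derive: recipes built
        from each published row return the generating parameters within the
        fitted confidence intervals at 2% noise."""
        rec = micellar_recipe(log_k, delta_h, seed=77)
        rng = rec.rng()
        curves = []
        for _ in range(3):
            gross, blank = simulate_titration(rec, rng=rng)
            heats_g = integrate_peaks(simulate_power_trace(gross.heats, rec.schedule, rec))
            heats_b = integrate_peaks(simulate_power_trace(blank.heats, rec.schedule, rec))
            from itcfit import TitrationCurve
            net = subtract_blank(TitrationCurve(rec.schedule, heats_g),
                                 TitrationCurve(rec.schedule, heats_b)).net
            curves.append((rec.schedule, net))
        res = OneSiteBindingModel(curves).fit()
        ci = res.conf_int()
        assert ci[0, 0] <= log_k <= ci[0, 1]
        assert ci[1, 0] <= delta_h <= ci[1, 1]
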