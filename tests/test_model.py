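import numpy as np
import pytest

from itcfit import (
    BindingParameters,
    IndeterminateParametersError,
    OneSiteBindingModel,
    micellar_recipe,
    predicted_heats,
    simulate_titration,
    subtract_blank,
)


def noiseless_model(log_k=5.1, delta_h=2.41, schedule=None):
    from itcfit import default_schedule
    s = schedule or default_schedule()
    return OneSiteBindingModel([(s, predicted_heats(s, BindingParameters(log_k, delta_h)))])


def net_curves(recipe, n_replicates=1):
    rng = recipe.rng()
    out = []
    for _ in range(n_replicates):
        g, b = simulate_titration(recipe, rng=rng)
        out.append((recipe.schedule, subtract_blank(g, b).net))
    return out


class TestObjective:
    def test_zero_at_generating_parameters(self):
        m = noiseless_model()
        assert m.objective_u(5.1, 2.41) == pytest.approx(0.0, abs=1e-25)

    def test_sum_of_squared_residuals(self):
        """One 10 µJ observation against a 7 µJ prediction gives U = 9 µJ²."""
        m = noiseless_model()
        q_pred = m.predict(5.1, 2.41)
        m2 = OneSiteBindingModel([(m.datasets[0].schedule, q_pred + 3e-6)])
        assert m2.objective_u(5.1, 2.41) == pytest.approx(25 * 9e-12, rel=1e-9)

    def test_grid_minimum_at_truth_for_noiseless_data(self):
        m = noiseless_model()
        u_true = m.objective_u(5.1, 2.41)
        for lk in range(1, 9):
            for dh in range(-50, 51, 10):
                assert m.objective_u(float(lk), float(dh)) >= u_true


class TestFit:
    def test_noiseless_recovery_to_machine_precision(self):
        res = noiseless_model().fit()
        assert res.params.log_k == pytest.approx(5.1, abs=1e-6)
        assert res.params.delta_h == pytest.approx(2.41, abs=1e-6)
        assert res.converged

    def test_noiseless_recovery_low_c(self):
        res = noiseless_model(log_k=2.5, delta_h=23.5).fit()
        assert res.params.log_k == pytest.approx(2.5, abs=1e-6)
        assert res.params.delta_h == pytest.approx(23.5, abs=1e-6)

    def test_all_zero_data_is_indeterminate(self, schedule):
        m = OneSiteBindingModel([(schedule, np.zeros(25))])
        with pytest.raises(IndeterminateParametersError):
            m.fit()

    def test_optimum_not_worse_than_any_multistart_seed(self):
        rec = micellar_recipe(5.1, 2.41, seed=3)
        m = OneSiteBindingModel(net_curves(rec))
        res = m.fit()
        dh0 = m._delta_h_seed()
        for lk in range(1, 9):
            assert res.objective_u <= m.objective_u(float(lk), dh0) + 1e-18

    def test_order_invariance(self):
        rec = micellar_recipe(5.1, 2.41, seed=9)
        curves = net_curves(rec, n_replicates=3)
        a = OneSiteBindingModel(curves).fit()
        b = OneSiteBindingModel(curves[::-1]).fit()
        assert a.params.log_k == pytest.approx(b.params.log_k, abs=1e-10)
        assert a.params.delta_h == pytest.approx(b.params.delta_h, abs=1e-10)

    def test_pooled_replicates_tighten_parameters(self):
        """Joint refinement of three replicates gives smaller sds than any
        single-titration fit, and no worse a per-dof objective."""
        wins = 0
        n_rep = 20
        for s in range(n_rep):
            rec = micellar_recipe(5.1, 2.41, seed=500 + s)
            curves = net_curves(rec, n_replicates=3)
            singles = [OneSiteBindingModel([c]).fit() for c in curves]
            joint = OneSiteBindingModel(curves).fit()
            sd_ok = all(joint.bse[i] < min(sf.bse[i] for sf in singles)
                        for i in (0, 1))
            u_ok = (joint.objective_u / joint.df_resid
                    <= max(sf.objective_u / sf.df_resid for sf in singles))
            wins += sd_ok and u_ok
        assert wins >= int(0.9 * n_rep)

    def test_low_c_inflates_relative_logk_uncertainty(self):
        """log K ≈ 2.5 at 0.2 mM host gives c ≈ 0.06: fits converge but the
        relative sd on log K is clearly larger than at log K = 5.1 (c ≈ 25),
        mirroring the precision pattern of the published tables."""
        ratios = []
        for s in range(6):
            lo = OneSiteBindingModel(net_curves(micellar_recipe(2.5, 23.5, seed=s))).fit()
            hi = OneSiteBindingModel(net_curves(micellar_recipe(5.1, 2.41, seed=100 + s))).fit()
            ratios.append((lo.bse[0] / lo.params.log_k)
                          / (hi.bse[0] / hi.params.log_k))
        assert np.median(ratios) > 1.5

    def test_confidence_interval_coverage(self):
        """Asymptotic 95% CIs cover the generating values at a near-nominal
        rate over simulated experiments spanning log K ∈ [2, 6]."""
        rng = np.random.default_rng(2024)
        n_exp = 60
        cover = np.zeros(2)
        for _ in range(n_exp):
            lk = rng.uniform(2, 6)
            dh = rng.uniform(-25, 25)
            rec = micellar_recipe(lk, dh, seed=int(rng.integers(2**31)))
            res = OneSiteBindingModel(net_curves(rec, n_replicates=3)).fit()
            ci = res.conf_int()
            cover += [ci[0, 0] <= lk <= ci[0, 1], ci[1, 0] <= dh <= ci[1, 1]]
        for rate in cover / n_exp:
            assert 0.85 <= rate <= 1.0


class TestResults:
    def test_summary_and_json_are_self_consistent(self):
        rec = micellar_recipe(5.1, 2.41, seed=21)
        res = OneSiteBindingModel(net_curves(rec)).fit()
        rec_json = res.to_json_record()
        assert rec_json["log_k"] == res.params.log_k
        assert rec_json["wiseman_c"] == pytest.approx(
            10 ** res.params.log_k * 2e-4)
        assert rec_json["n_points"] == 25
        text = res.summary()
        assert "log K" in text and "kJ/mol" in text

    def test_delta_s_uncertainty_propagates_covariance(self):
        rec = micellar_recipe(5.1, 2.41, seed=21)
        res = OneSiteBindingModel(net_curves(rec)).fit()
        naive = np.sqrt((8.314462618 * np.log(10) * res.bse[0]) ** 2
                        + (1000 / 298.15 * res.bse[1]) ** 2)
        assert res.delta_s.sd > 0
        assert res.delta_s.sd != pytest.approx(naive, rel=1e-6)  # corr ≠ 0
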