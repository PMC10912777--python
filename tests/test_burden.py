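"""Analytical burden calculus against hand values and simulation."""

from dataclasses import replace

import numpy as np
import pytest

from rcell import fast_steady_state, no_burden_reference
from rcell.burden import (
    ControllerDesign,
    controller_setpoints,
    lambda_ratio_from_phi,
    native_burden_sum,
    operation_range,
    optimal_burden,
    predict_lambda,
    predict_phi_X,
    production_rate_curve,
    translational_burden,
)
from rcell.circuits import CircuitSpec, GeneSpec, build_aif_controller


class TestTranslationalBurden:
    def test_zero_dose_zero_burden(self, ref, poi_gene):
        assert translational_burden(replace(poi_gene, c=0.0), ref) == 0.0

    def test_hand_value(self, ref):
        """xi = F*c*alpha/k_NB = 1*10*100/500 = 2 for made-up kinetics."""
        from rcell.simulate import NoBurdenReference
        toy = NoBurdenReference(sigma=0.5, eps_NB=ref.eps_NB, F_r_NB=ref.F_r_NB,
                                lambda_NB=ref.lambda_NB, k_NB={"g": 500.0})
        gene = GeneSpec(name="g", c=10.0, alpha=100.0)
        assert translational_burden(gene, toy) == pytest.approx(2.0)

    def test_linear_in_dose(self, ref, poi_gene):
        x1 = translational_burden(replace(poi_gene, c=7.0), ref)
        x2 = translational_burden(replace(poi_gene, c=14.0), ref)
        assert x2 == pytest.approx(2 * x1)


class TestPhiPrediction:
    def test_limits(self, params, ref):
        assert predict_phi_X(0.0, params, ref) == 0.0
        assert predict_phi_X(1e12, params, ref) == pytest.approx(1.0, abs=1e-3)

    def test_half_saturation_at_native_sum(self, params, ref):
        S = native_burden_sum(params, ref)
        assert predict_phi_X(S, params, ref) == pytest.approx(0.5)

    def test_rejects_negative(self, params, ref):
        with pytest.raises(ValueError):
            predict_phi_X(-1.0, params, ref)


class TestLambdaPrediction:
    def test_strictly_decreasing(self, params, ref):
        xis = np.geomspace(1.0, 1e6, 20)
        lams = [predict_lambda(x, params, ref) for x in xis]
        assert np.all(np.diff(lams) < 0)
        assert lams[-1] > 0

    def test_matches_no_burden_growth(self, params, ref):
        assert predict_lambda(0.0, params, ref) == pytest.approx(
            ref.lambda_NB, rel=0.05)

    def test_half_growth_at_native_sum(self, params, ref):
        S = native_burden_sum(params, ref)
        lam0 = predict_lambda(0.0, params, ref)
        assert predict_lambda(S, params, ref) == pytest.approx(lam0 / 2)


class TestLinearGrowthLaw:
    @pytest.mark.parametrize("phi_X, phi_q, expected", [
        (0.0, 0.59, 1.0),
        (0.41, 0.59, 0.0),
        (0.25, 0.59, 0.3902439),
    ])
    def test_values(self, phi_X, phi_q, expected):
        assert lambda_ratio_from_phi(phi_X, phi_q) == pytest.approx(expected, rel=1e-6)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            lambda_ratio_from_phi(0.5, 0.59)

    def test_consistency_chain(self, params, ref, rng):
        """phi and lambda predictions jointly satisfy the linear law exactly."""
        lam0 = predict_lambda(0.0, params, ref)
        for xi in rng.uniform(10.0, 3e5, size=20):
            phi_total = (1.0 - params.phi_q) * predict_phi_X(xi, params, ref)
            ratio = lambda_ratio_from_phi(phi_total, params.phi_q)
            assert ratio == pytest.approx(predict_lambda(xi, params, ref) / lam0,
                                          rel=1e-12)


class TestSweepAgreement:
    def test_predictions_track_simulation(self, params, ref, poi_gene):
        """Across the 1-1100 nM dose sweep the analytics stay within 10%."""
        for c in np.geomspace(1.0, 1100.0, 15):
            gene = replace(poi_gene, c=float(c))
            ss = fast_steady_state(params, CircuitSpec(genes=[gene], name="s"))
            xi = translational_burden(gene, ref)
            phi_sim = gene.n * ss[f"p_{gene.name}"] / params.M
            assert predict_phi_X(xi, params, ref) == pytest.approx(phi_sim, rel=0.10)
            assert predict_lambda(xi, params, ref) == pytest.approx(
                ss.derived.lam, rel=0.10)


class TestOptimalBurden:
    def test_no_death_gives_native_sum(self, params, ref):
        assert optimal_burden(0.0, params, ref) == pytest.approx(
            native_burden_sum(params, ref))

    def test_vanishes_as_death_approaches_growth(self, params, ref):
        xi = optimal_burden(ref.lambda_NB * 0.999, params, ref)
        assert xi < 1e-3 * native_burden_sum(params, ref)

    def test_rejects_nonviable_population(self, params, ref):
        with pytest.raises(ValueError):
            optimal_burden(ref.lambda_NB * 1.01, params, ref)

    def test_matches_numerical_argmax(self, params, ref, poi_gene):
        """Analytic optimum within 1% of the production-curve argmax."""
        delta = 0.25
        xi_max = optimal_burden(delta, params, ref)
        curve = production_rate_curve(np.geomspace(1.0, 1100.0, 60), delta,
                                      params, ref, poi_gene)
        assert xi_max == pytest.approx(curve["xi_argmax"], rel=0.01)

    def test_production_curve_unimodal(self, params, ref, poi_gene):
        curve = production_rate_curve(np.geomspace(1.0, 1100.0, 40), 0.25,
                                      params, ref, poi_gene)
        mu = curve["mu"]
        i = int(np.argmax(mu))
        assert 0 < i < len(mu) - 1
        assert np.all(np.diff(mu[:i + 1]) > 0)
        assert np.all(np.diff(mu[i:]) < 0)

    def test_no_burden_no_production(self, params, ref, poi_gene):
        curve = production_rate_curve([1e-9], 0.25, params, ref, poi_gene)
        # peak production is ~1e8 nM-aa/h; at vanishing dose it is ~1e-3
        assert curve["mu"][0] < 1.0


def _design(**kw):
    base = dict(u=0.4, K_sens=3722.0, kappa=1.0e4, chi=3.0e5,
                c_sens=10.0, alpha_sens=60.0)
    base.update(kw)
    return ControllerDesign(**base)


class TestControllerSetpoints:
    def test_setpoint_vanishes_as_u_approaches_one(self, params, ref):
        lam_hi = controller_setpoints(_design(u=0.5), params, ref).lambda_setpoint
        lam_lo = controller_setpoints(_design(u=0.99), params, ref).lambda_setpoint
        assert lam_lo < 0.05 * lam_hi

    def test_inverse_in_sensor_expression(self, params, ref):
        a = controller_setpoints(_design(), params, ref).lambda_setpoint
        b = controller_setpoints(_design(alpha_sens=120.0), params, ref).lambda_setpoint
        assert b == pytest.approx(a / 2, rel=1e-6)

    def test_u_bounds_enforced(self):
        with pytest.raises(ValueError):
            _design(u=1.2)

    def test_predicts_simulated_closed_loop_growth(self, params, ref):
        """Ideal-annihilation analytics land near the simulated closed loop."""
        from rcell import steady_state
        d = controller_setpoints(_design(), params, ref)
        ss = steady_state(params, build_aif_controller(), horizon=200.0)
        assert d.lambda_setpoint == pytest.approx(ss.derived.lam, rel=0.10)
        assert d.D_setpoint == pytest.approx(ss.derived.D, rel=0.15)
        assert d.p_sens_setpoint == pytest.approx(ss["p_sens"], rel=0.15)


class TestOperationRange:
    def test_empty_disturbance_trivially_mitigable(self, params, ref):
        lhs, rhs, ok = operation_range(_design(), [], params, ref)
        assert lhs == 0.0
        assert ok == (rhs >= 0.0)

    def test_additive_over_genes(self, params, ref):
        g1 = GeneSpec(name="d1", c=20.0, alpha=500.0)
        g2 = GeneSpec(name="d2", c=10.0, alpha=800.0)
        l1, _, _ = operation_range(_design(), [g1], params, ref)
        l2, _, _ = operation_range(_design(), [g2], params, ref)
        l12, _, _ = operation_range(_design(), [g1, g2], params, ref)
        assert l12 == pytest.approx(l1 + l2, rel=1e-9)

    def test_boundary_separates_simulated_regimes(self, params):
        """Inside the range the closed loop is near-flat; outside it falls
        at the open-loop slope."""
        from rcell.scenarios import run_aif_range
        tables = run_aif_range(sigma=0.5)
        df = tables["range"]
        inside = df[df.within_range]
        outside = df[~df.within_range]
        assert len(inside) >= 3 and len(outside) >= 2
        assert (1 - inside["p_sens_rel_closed"]).abs().max() < 0.10
        # outside: closed-loop decline per decade of dose approaches open-loop's
        for col in ("p_sens_rel_closed", "p_sens_rel_open"):
            outside = outside.assign(**{col + "_log": np.log(outside[col])})
        x = np.log(outside["c_dist_nM"])
        slope_cl = np.polyfit(x, np.log(outside["p_sens_rel_closed"]), 1)[0]
        slope_ol = np.polyfit(x, np.log(outside["p_sens_rel_open"]), 1)[0]
        assert slope_cl == pytest.approx(slope_ol, rel=0.5)
        assert slope_cl < -0.1
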