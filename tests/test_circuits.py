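"""Heterologous circuit framework and the case-study builders."""

from dataclasses import replace

import numpy as np
import pytest

from rcell import (
    build_aif_controller,
    build_constitutive_gene,
    build_disturbance_gene,
    build_inducible_module,
    build_t7_self_activator,
    build_winner_takes_all,
    circuit_rhs,
    fast_steady_state,
    host_rhs,
    integrate,
    multi_start_steady_states,
    steady_state,
)
from rcell.circuits import (
    CircuitConfigError,
    CircuitSpec,
    EMPTY_CIRCUIT,
    GeneSpec,
    RegulationSpec,
)
from rcell.simulate import default_initial_state


class TestRegulation:
    def test_constitutive_is_one(self):
        assert RegulationSpec().evaluate({}) == 1.0

    @pytest.mark.parametrize("kind", ["hill_activation", "hill_repression"])
    def test_bounded_in_unit_interval(self, kind, rng):
        reg = RegulationSpec(kind=kind, regulator="p", K=100.0, hill=2.0,
                             baseline=0.05)
        for p in rng.uniform(0, 1e6, size=50):
            F = reg.evaluate({"p": p})
            assert 0.0 <= F <= 1.0

    def test_activation_repression_complementary_at_K(self):
        act = RegulationSpec(kind="hill_activation", regulator="p", K=50.0, hill=1.0)
        rep = RegulationSpec(kind="hill_repression", regulator="p", K=50.0, hill=1.0)
        assert act.evaluate({"p": 50.0}) == pytest.approx(0.5)
        assert rep.evaluate({"p": 50.0}) == pytest.approx(0.5)

    def test_unknown_regulator_raises(self):
        reg = RegulationSpec(kind="hill_activation", regulator="ghost")
        with pytest.raises(CircuitConfigError):
            reg.evaluate({"p": 1.0})

    def test_unknown_kind_rejected(self):
        with pytest.raises(CircuitConfigError):
            RegulationSpec(kind="linear")


class TestCircuitSpec:
    def test_duplicate_names_rejected(self):
        with pytest.raises(CircuitConfigError):
            CircuitSpec(genes=[GeneSpec(name="x"), GeneSpec(name="x")])

    def test_annihilation_must_reference_declared_species(self):
        with pytest.raises(CircuitConfigError):
            CircuitSpec(genes=[GeneSpec(name="x")],
                        annihilations=[("m_x", "ghost", 1.0)])

    def test_species_ordering(self):
        spec = build_aif_controller()
        names = spec.species_names()
        assert names[:2] == ["m_sens", "p_sens"]
        assert "anti" in names


class TestNullCircuitEquivalence:
    def test_rhs_identical(self, params, rng):
        for _ in range(10):
            x = rng.uniform(1.0, 1e5, size=6)
            from rcell.params import HostState
            host = HostState(*x)
            dhost, dcirc = circuit_rhs(host, np.empty(0), params, EMPTY_CIRCUIT)
            assert np.array_equal(dhost, host_rhs(host, params))
            assert dcirc.size == 0

    def test_zero_copy_number_gene_reproduces_host(self, params, host_ss):
        spec = build_constitutive_gene(c=1e-9)
        ss = steady_state(params, spec, horizon=200.0, tol=1e-9)
        assert ss.derived.lam == pytest.approx(host_ss.derived.lam, rel=1e-6)


class TestConstitutiveGene:
    def test_structure(self):
        spec = build_constitutive_gene()
        assert len(spec.genes) == 1 and not spec.rnas
        assert spec.genes[0].regulation.evaluate({}) == 1.0

    def test_growth_strictly_decreasing_in_dose(self, params):
        lams = [fast_steady_state(params, build_constitutive_gene(c=c)).derived.lam
                for c in np.geomspace(1.0, 1100.0, 8)]
        assert np.all(np.diff(lams) < 0)

    def test_resource_monotonicity_D_increases(self, params, host_ss_fast):
        ss = fast_steady_state(params, build_constitutive_gene(c=100.0))
        assert ss.derived.D > host_ss_fast.derived.D
        assert ss.derived.lam < host_ss_fast.derived.lam

    def test_shared_denominator_identity(self, params):
        """D equals 1 + (1/(1-phi_q)) * sum m_j/k_j over native + circuit genes."""
        spec = build_constitutive_gene(c=100.0)
        ss = steady_state(params, spec, horizon=100.0)
        d = ss.derived
        w = (ss["m_a"] / d.k["a"] + ss["m_r"] / d.k["r"]
             + ss["m_x"] / d.k["x"])
        assert d.D == pytest.approx(1.0 + w / (1.0 - params.phi_q), rel=1e-12)

    def test_mass_convergence_includes_circuit_protein(self, params):
        spec = build_constitutive_gene(c=100.0)
        ss = steady_state(params, spec, horizon=200.0, tol=1e-9)
        mass = ss.modeled_protein_mass()
        assert mass == pytest.approx(params.M, rel=1e-3)


def _wta_outcome(params, f1, f2, k_plus=60.0):
    spec0 = build_winner_takes_all(0.0, 0.0, k_plus=k_plus)
    base = steady_state(params, spec0, horizon=72.0)
    spec = build_winner_takes_all(f1, f2, k_plus=k_plus)
    ss = steady_state(params, spec, horizon=72.0, init=base.x)
    K = spec.genes[0].regulation.K
    iK = spec.genes[0].regulation.inducer_K
    return ss, ss["p_s1"] * f1 / (f1 + iK) > K, ss["p_s2"] * f2 / (f2 + iK) > K


class TestWinnerTakesAll:
    def test_symmetric_inducers_co_activate(self, params):
        _, a1, a2 = _wta_outcome(params, 20.0, 20.0)
        assert a1 and a2

    def test_asymmetric_inducers_exclude_slow_switch(self, params):
        ss, a1, a2 = _wta_outcome(params, 800.0, 20.0)
        assert a1 and not a2
        assert ss["p_s1"] > 10 * ss["p_s2"]

    def test_effect_fades_as_resource_demand_shrinks(self, params):
        """Weakening both RBSs removes the resource-mediated suppression."""
        ratios = []
        for factor in (1.0, 5.0):
            co, *_ = _wta_outcome(params, 20.0, 20.0, k_plus=60.0 / factor)
            ex, *_ = _wta_outcome(params, 800.0, 20.0, k_plus=60.0 / factor)
            ratios.append(ex["p_s2"] / co["p_s2"])
        assert ratios[0] < 0.2          # strong suppression at full demand
        assert ratios[1] > 0.8          # nearly none at low demand

    def test_negative_inducer_rejected(self):
        with pytest.raises(CircuitConfigError):
            build_winner_takes_all(-1.0, 20.0)


class TestT7SelfActivator:
    def test_transcription_not_growth_coupled(self, params):
        """The T7 synthesis term is independent of the host growth rate."""
        from rcell.params import HostState
        spec = build_t7_self_activator()
        circ = np.array([100.0, 1000.0])
        fast = HostState(2e4, 1.5e4, 1.3e6, 1.1e5, 2500.0, 1500.0)
        slow = HostState(2e3, 1.5e3, 1.3e6, 1.1e5, 800.0, 1500.0)
        for host in (fast, slow):
            _, dcirc = circuit_rhs(host, circ, params, spec)
            g = spec.genes[0]
            lam = 0.0  # synthesis term only: txn - (beta+lam)m, lam-free txn
            txn = dcirc[0] + (g.beta + _growth(host, params, spec, circ)) * circ[0]
            F = g.regulation.evaluate({"m_t7": circ[0], "p_t7": circ[1]})
            assert txn == pytest.approx(F * g.c * g.alpha, rel=1e-9)

    def test_two_start_bistability(self, params):
        spec = build_t7_self_activator()
        lo = default_initial_state(params, spec)
        hi = lo.copy()
        hi[6], hi[7] = 3.0e3, 2.5e5
        states = multi_start_steady_states(params, spec, [lo, hi], horizon=240.0)
        assert len(states) == 2
        lams = sorted(s.derived.lam for s in states)
        assert lams[1] > 2 * lams[0]    # distinct growth rates

    def test_weak_feedback_without_toxicity_is_monostable(self, params):
        spec = build_t7_self_activator(toxicity_K=None, alpha=300.0)
        lo = default_initial_state(params, spec)
        hi = lo.copy()
        hi[7] = 2.5e5
        states = multi_start_steady_states(params, spec, [lo, hi], horizon=240.0)
        assert len(states) == 1


def _growth(host, params, spec, circ):
    from rcell.simulate import _derived_from_vector
    x = np.concatenate([host.as_array(), circ])
    return _derived_from_vector(x, params, spec, None).lam


class TestAifController:
    def test_structure(self):
        spec = build_aif_controller()
        assert {g.name for g in spec.genes} == {"sens", "act", "amp"}
        assert [r.name for r in spec.rnas] == ["anti"]
        assert spec.annihilations[0][:2] == ("m_act", "anti")

    def test_setpoint_undefined_outside_unit_interval(self):
        for u in (0.0, 1.0, 1.5):
            with pytest.raises(CircuitConfigError):
                build_aif_controller(u=u)

    def test_annihilation_balance_sets_sensor_level(self, params):
        """The sensor settles where F_anti(p_sens) = u minus the leak term.

        Subtracting the actuator and annihilator steady-state balances gives
        F_anti(p_sens) = u - (beta+lam)*(m_act - m_anti)/(kappa*lam); with
        vanishing degradation/dilution relative to annihilation this pins
        p_sens at the ideal setpoint K_sens*(1-u)/u.
        """
        u, K_sens, kappa = 0.4, 3722.0, 1.0e4
        spec = build_aif_controller(u=u, K_sens=K_sens, kappa=kappa)
        ss = steady_state(params, spec, horizon=200.0)
        lam = ss.derived.lam
        beta = spec.genes[1].beta  # act gene
        leak = (beta + lam) * (ss["m_act"] - ss["anti"]) / (kappa * lam)
        F_anti = K_sens / (K_sens + ss["p_sens"])
        assert F_anti == pytest.approx(u - leak, rel=1e-4)
        # the leak is small, so the ideal setpoint is nearly attained
        assert ss["p_sens"] == pytest.approx(K_sens * (1 - u) / u, rel=0.15)

    def test_disturbance_rejection_beats_open_loop(self, params):
        from rcell.scenarios import run_aif_step
        tables = run_aif_step(sigma=0.5)
        s = tables["summary"].iloc[0]
        assert s["adaptation_error_closed"] < s["adaptation_error_open"]
        assert s["error_ratio"] <= 0.6

    def test_amplifier_gain_reduces_adaptation_error(self, params):
        errors = []
        for chi in (3.0e4, 1.0e5, 3.0e5):
            undisturbed = steady_state(params, build_aif_controller(chi=chi),
                                       horizon=300.0)
            spec = build_aif_controller(chi=chi).merged(
                build_disturbance_gene(c=100.0), name="x")
            disturbed = steady_state(params, spec, horizon=300.0)
            assert undisturbed.converged and disturbed.converged
            errors.append(abs(disturbed["p_sens"] / undisturbed["p_sens"] - 1.0))
        assert errors[0] > errors[1] > errors[2]


class TestInducibleModule:
    def test_no_inducer_no_output(self, params):
        spec = build_inducible_module(inducer=0.0, baseline=0.0)
        ss = steady_state(params, spec, horizon=100.0)
        assert ss["p_x"] == pytest.approx(0.0, abs=1e-6)

    def test_induction_curve_monotone_saturating(self, params):
        fs = np.geomspace(5.0, 5000.0, 7)
        px = [steady_state(params, build_inducible_module(inducer=f),
                           horizon=150.0)["p_x"] for f in fs]
        assert np.all(np.diff(px) > -1e-6)
        # saturation: last doubling gains proportionally little
        assert px[-1] / px[-2] < px[1] / px[0]


class TestDisturbanceGene:
    def test_onset_time_gates_transcription(self, params):
        spec = build_disturbance_gene(onset_time=10.0)
        traj = integrate(params, spec, t_span=20.0,
                         t_eval=np.linspace(0, 20, 81))
        m = traj["m_dist"]
        before = m[traj.times < 9.9]
        after = m[traj.times > 15.0]
        assert np.all(before < 1e-9)
        assert np.all(after > 1.0)
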