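"""Rate laws, apparent dissociation constants and the host right-hand side."""

import numpy as np
import pytest

from rcell import (
    ChloramphenicolParams,
    HostParams,
    HostState,
    apparent_dissociation_constants,
    chloramphenicol_rhs,
    derived_rates,
    fast_steady_state,
    host_rhs,
)
from rcell.params import InvalidParameterError, T_CAP


class TestApparentDissociationConstants:
    @pytest.mark.parametrize(
        "eps, k_minus, k_plus, n, expected",
        [
            (0.0, 60.0, 60.0, 300.0, 1.0),        # elongation term vanishes
            (300.0, 0.0, 1.0, 300.0, 1.0),        # eps/n = k_plus, k_minus = 0
            (7.2e4, 60.0, 60.0, 300.0, 5.0),      # (60 + 240)/60
        ],
    )
    def test_hand_values(self, eps, k_minus, k_plus, n, expected):
        k = apparent_dissociation_constants(eps, {"g": (k_minus, k_plus, n)})
        assert k["g"] == pytest.approx(expected)

    def test_rejects_nonpositive_k_plus(self):
        with pytest.raises(InvalidParameterError):
            apparent_dissociation_constants(1.0, {"g": (60.0, 0.0, 300.0)})

    def test_rejects_negative_eps(self):
        with pytest.raises(ValueError):
            apparent_dissociation_constants(-1.0, {"g": (60.0, 60.0, 300.0)})

    def test_chloramphenicol_adds_inactivation_term(self):
        cm = ChloramphenicolParams(h_cm=2.0, k_cm=0.3)
        k0 = apparent_dissociation_constants(0.0, {"g": (60.0, 60.0, 300.0)})
        k1 = apparent_dissociation_constants(0.0, {"g": (60.0, 60.0, 300.0)}, cm)
        assert k1["g"] - k0["g"] == pytest.approx(0.6 / 60.0)


class TestDerivedRates:
    def test_zero_precursors_stop_translation(self, params):
        s = HostState(m_a=100, m_r=100, p_a=1e5, R=1e4, t_c=0.0, t_u=50.0)
        d = derived_rates(s, params)
        assert d.eps == 0.0 and d.lam == 0.0

    def test_half_saturations(self, params):
        s = HostState(m_a=10, m_r=10, p_a=1e5, R=1e4,
                      t_c=params.K_eps, t_u=params.K_nu)
        d = derived_rates(s, params)
        assert d.eps == pytest.approx(params.eps_max / 2)
        assert d.nu == pytest.approx(params.nu_max * params.sigma / 2)

    def test_regulation_half_saturation_at_T_equals_tau(self, params):
        s = HostState(m_a=10, m_r=10, p_a=1e5, R=1e4,
                      t_c=params.tau * 50.0, t_u=50.0)
        d = derived_rates(s, params)
        assert d.F_r == pytest.approx(0.5)
        assert d.psi == pytest.approx(params.psi_max / 2)

    def test_no_transcripts_means_no_translation(self, params):
        s = HostState(m_a=0, m_r=0, p_a=1e5, R=1e4, t_c=100, t_u=100)
        d = derived_rates(s, params)
        assert d.D == pytest.approx(1.0)
        assert d.B == 0.0 and d.lam == 0.0

    def test_T_capped_when_uncharged_pool_empty(self, params):
        s = HostState(m_a=10, m_r=10, p_a=1e5, R=1e4, t_c=100.0, t_u=0.0)
        d = derived_rates(s, params)
        assert d.T == T_CAP
        assert d.F_r == pytest.approx(1.0)

    def test_negative_state_rejected(self, params):
        s = HostState(m_a=-1.0, m_r=10, p_a=1e5, R=1e4, t_c=10, t_u=10)
        with pytest.raises(ValueError):
            derived_rates(s, params)

    def test_invariants_on_random_states(self, params, rng):
        for _ in range(50):
            s = HostState(*rng.uniform(0.1, 1e5, size=6))
            d = derived_rates(s, params)
            assert 0.0 <= d.F_r <= 1.0
            assert d.D >= 1.0
            assert 0.0 <= d.B <= s.R + 1e-12
            assert d.lam == pytest.approx(d.eps * d.B / params.M)


class TestHostRhs:
    def test_origin_is_absorbing(self, params):
        s = HostState(0, 0, 0, 0, 0, 0)
        assert np.allclose(host_rhs(s, params), 0.0)

    def test_steady_state_is_fixed_point(self, params, host_ss):
        dx = host_rhs(host_ss.host, params)
        scale = np.maximum(np.abs(host_ss.x[:6]), 1.0)
        assert np.all(np.abs(dx) / scale < 1e-6)

    def test_protein_mass_balance_identity(self, params, rng):
        """n_a*dp_a + n_r*dR = eps*B*(1 - modeled protein mass / M) at any state."""
        for _ in range(25):
            s = HostState(*rng.uniform(1.0, 1e5, size=6))
            d = derived_rates(s, params)
            dx = host_rhs(s, params)
            lhs = params.n_a * dx[2] + params.n_r * dx[3]
            mass = params.n_a * s.p_a + params.n_r * s.R
            rhs = d.eps * d.B * (1.0 - mass / params.M)
            assert lhs == pytest.approx(rhs, rel=1e-10, abs=1e-8)


class TestChloramphenicol:
    def test_null_extension_recovers_host(self, params, rng):
        cm = ChloramphenicolParams(h_cm=0.0)
        for _ in range(10):
            vals = rng.uniform(1.0, 1e5, size=6)
            s = HostState(*vals, B_cm=0.0)
            dx7 = chloramphenicol_rhs(s, params, cm)
            dx6 = host_rhs(HostState(*vals), params)
            assert np.allclose(dx7[:6], dx6)
            assert dx7[6] == 0.0

    def test_negative_dose_rejected(self):
        with pytest.raises(InvalidParameterError):
            ChloramphenicolParams(h_cm=-1.0)

    def test_growth_decreases_with_dose(self, params):
        lams = [
            fast_steady_state(params, cm=ChloramphenicolParams(h_cm=h)).derived.lam
            if h > 0 else fast_steady_state(params).derived.lam
            for h in (0.0, 1.0, 2.0, 4.0, 8.0)
        ]
        assert np.all(np.diff(lams) < 0)

    def test_second_growth_law_geometry(self, params):
        """Up to 4 uM, ribosome content rises as inhibition slows growth."""
        lams, phis = [], []
        for h in (0.0, 1.0, 2.0, 4.0):
            cm = ChloramphenicolParams(h_cm=h) if h > 0 else None
            ss = fast_steady_state(params, cm=cm)
            B_cm = ss["B_cm"] if h > 0 else 0.0
            lams.append(ss.derived.lam)
            phis.append(params.n_r * (ss["R"] + B_cm) / params.M)
        assert np.all(np.diff(lams) < 0)
        assert np.all(np.diff(phis) > 0)


class TestPropertyBased:
    from hypothesis import given, settings, strategies as st

    conc = st.floats(min_value=1e-3, max_value=1e6, allow_nan=False)

    @given(m_a=conc, m_r=conc, p_a=conc, R=conc, t_c=conc, t_u=conc)
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_mass_balance_identity_everywhere(self, m_a, m_r, p_a, R, t_c, t_u):
        """n_a*dp_a + n_r*dR = eps*B*(1 - mass/M) holds at every state."""
        from rcell import default_host_params
        params = default_host_params()
        s = HostState(m_a, m_r, p_a, R, t_c, t_u)
        d = derived_rates(s, params)
        dx = host_rhs(s, params)
        lhs = params.n_a * dx[2] + params.n_r * dx[3]
        mass = params.n_a * s.p_a + params.n_r * s.R
        rhs = d.eps * d.B * (1.0 - mass / params.M)
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-6)

    @given(t_c=conc, t_u=st.floats(min_value=0.0, max_value=1e6,
                                   allow_nan=False))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_derived_bounds_hold(self, t_c, t_u):
        from rcell import default_host_params
        params = default_host_params()
        s = HostState(10.0, 10.0, 1e5, 1e4, t_c, t_u)
        d = derived_rates(s, params)
        assert 0.0 <= d.F_r <= 1.0
        assert 0.0 <= d.eps <= params.eps_max
        assert 0.0 <= d.nu <= params.nu_max
        assert d.D >= 1.0


class TestHostParamsValidation:
    def test_rejects_bad_phi_q(self, params):
        with pytest.raises(InvalidParameterError):
            params.replace(phi_q=1.5)

    def test_rejects_bad_sigma(self, params):
        with pytest.raises(InvalidParameterError):
            params.replace(sigma=-0.1)

    def test_rejects_nonpositive_rate(self, params):
        with pytest.raises(InvalidParameterError):
            params.replace(nu_max=0.0)

    def test_native_copy_number_convention(self, params):
        assert params.c_a == 1.0 and params.c_r == 1.0
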