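"""Endocannabinoid cascade: DAGL activation, 2-AG/AEA balance, CB1R kinetics."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from striatal_stdp.ecb import (
    EcbState,
    aea_rhs,
    cb1r_rhs,
    dag_and_2ag_rhs,
    dagl_activation_rhs,
    ecb_concentration,
)


def _es(DAG=0.0, AG2=0.0, AEA=0.0, phi=0.0, x=0.0, d=0.0):
    return EcbState(DAG=DAG, AG2=AG2, AEA=AEA, phi_DAGL=phi, x_CB1R=x, d_CB1R=d)


class TestDaglActivation:
    def test_rest_fixed_point(self, params):
        assert dagl_activation_rhs(0.0, 0.0, params) == 0.0

    def test_clamped_calcium_steady_state(self, params):
        # analytic fixed point phi* = r_k C^n / (r_k C^n + r_p)
        C = 0.8
        phi_star = (
            params.r_k * C**params.n_c / (params.r_k * C**params.n_c + params.r_p)
        )
        assert dagl_activation_rhs(phi_star, C, params) == pytest.approx(0.0, abs=1e-12)
        # and simulation relaxes onto it
        sol = solve_ivp(lambda t, y: [dagl_activation_rhs(y[0], C, params)], (0, 20), [0.0],
                        rtol=1e-10, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(phi_star, rel=1e-6)

    def test_saturated_decays_at_rp(self, params):
        assert dagl_activation_rhs(1.0, 3.0, params) == pytest.approx(-params.r_p)


class TestDagAnd2ag:
    def test_empty_pools(self, params):
        dDAG, dAG2 = dag_and_2ag_rhs(_es(AG2=0.3), R_P=0.0, params=params)
        assert dDAG == 0.0
        assert dAG2 == pytest.approx(-params.r_MAGL * 0.3)

    def test_magl_block_makes_2ag_nondecreasing(self, params):
        p = params.replace(allow_zero=True, r_MAGL=0.0)
        s = _es(DAG=1.0, AG2=2.0, phi=0.5)
        _, dAG2 = dag_and_2ag_rhs(s, R_P=0.0, params=p)
        assert dAG2 > 0.0

    def test_mass_bookkeeping(self, params):
        # with DAGK and MAGL off, d(DAG + 2AG)/dt equals the production rate
        p = params.replace(allow_zero=True, r_DAGK=1e-30, r_MAGL=1e-30)
        s = _es(DAG=0.7, AG2=0.2, phi=0.9)
        dDAG, dAG2 = dag_and_2ag_rhs(s, R_P=1.25, params=p)
        assert dDAG + dAG2 == pytest.approx(1.25)


class TestAea:
    def test_decay_to_zero_without_calcium(self, params):
        sol = solve_ivp(lambda t, y: [aea_rhs(y[0], 0.0, params)], (0, 200), [1.0],
                        rtol=1e-10, atol=1e-12)
        assert sol.y[0, -1] < 1e-6

    def test_subcritical_steady_state(self, params):
        # fixed point of nu C = r A/(K+A):  A* = nu C K / (r - nu C)
        C = 0.5 * params.r_FAAH / params.nu_AT * 0.4
        a_star = (
            params.nu_AT * C * params.K_FAAH / (params.r_FAAH - params.nu_AT * C)
        )
        assert aea_rhs(a_star, C, params) == pytest.approx(0.0, abs=1e-12)
        sol = solve_ivp(lambda t, y: [aea_rhs(y[0], C, params)], (0, 500), [0.0],
                        rtol=1e-10, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(a_star, rel=1e-5)

    def test_supercritical_growth(self, params):
        # if nu C >= r_FAAH degradation saturates and AEA grows without bound
        C = 1.2 * params.r_FAAH / params.nu_AT
        assert aea_rhs(1e6, C, params) > 0.0


class TestCb1r:
    def test_rest_fixed_point(self, params):
        dx, dd = cb1r_rhs(_es(), params)
        assert dx == 0.0 and dd == 0.0

    def test_state_conservation_along_trajectory(self, params):
        # x+d+i = 1 is built in; integrating (x, d) keeps both in [0, 1]
        ecb_t = lambda t: 2.0 * np.exp(-t)  # decaying agonist pulse

        def rhs(t, y):
            s = _es(AG2=ecb_t(t), x=y[0], d=y[1])
            return cb1r_rhs(s, params)

        sol = solve_ivp(rhs, (0, 50), [0.0, 0.0], rtol=1e-10, atol=1e-12)
        x, d = sol.y
        assert (x >= -1e-9).all() and (d >= -1e-9).all()
        assert (x + d <= 1 + 1e-9).all()

    def test_clamped_agonist_fixed_point(self, params):
        # analytic steady state of the three-state scheme at constant eCB = E
        E = 1.5
        a, b, g, e = (params.alpha_CB1R, params.beta_CB1R, params.gamma_CB1R,
                      params.epsilon_CB1R)
        x_star = a * E / (a * E * (1 + g / e) + b + g)
        d_star = g * x_star / e
        dx, dd = cb1r_rhs(_es(AG2=E, x=x_star, d=d_star), params)
        assert dx == pytest.approx(0.0, abs=1e-12)
        assert dd == pytest.approx(0.0, abs=1e-12)

    def test_aea_partial_agonism_factor(self, params):
        assert ecb_concentration(1.0, 1.0, params) == pytest.approx(1.0 + params.A_AEA)
        assert params.A_AEA == 0.10
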