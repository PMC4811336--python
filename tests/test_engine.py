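"""Simulation engine: steady state, integration, reproducibility."""

import numpy as np
import pytest

from striatal_stdp import build_stdp_protocol, run_protocol, weight_change
from striatal_stdp.engine import (
    N_STATE,
    STATE_NAMES,
    full_rhs,
    steady_state_init,
)
from striatal_stdp.stimuli import ProtocolSpec


@pytest.fixture(scope="module")
def rest(params):
    return steady_state_init(params)


class TestSteadyState:
    def test_resting_point_properties(self, params, rest):
        names = list(STATE_NAMES)
        assert rest[names.index("V")] == pytest.approx(params.V_L, abs=2.0)
        assert rest[names.index("C")] == pytest.approx(params.Ca_b, abs=0.05)
        assert rest[names.index("C_ER")] > rest[names.index("C")]  # loaded store
        assert rest[names.index("W_pre")] == 1.0

    def test_rhs_vanishes_at_rest(self, params, rest):
        empty = ProtocolSpec((), (), float("nan"), 0, 1.0, "pre-only")
        dy = full_rhs(0.0, rest, params, empty)
        scale = np.maximum(np.abs(rest), 1e-3)
        assert np.max(np.abs(dy) / scale) < 1e-8

    def test_stationary_under_long_unstimulated_integration(self, params, rest):
        empty = ProtocolSpec((), (), float("nan"), 0, 1.0, "pre-only")
        res = run_protocol(params, empty, settle_time=100.0, record=False)
        drift = np.abs(res.states[-1] - rest) / np.maximum(np.abs(rest), 1e-3)
        assert drift.max() < 1e-3
        assert res.w_total == pytest.approx(1.0, abs=1e-4)


class TestModularKernelAgreement:
    def test_flat_rhs_matches_modular_operations(self, params, rest, rng):
        """The compiled right-hand side must equal the composition of the
        per-module operations at random state points."""
        from striatal_stdp import calcium as calc, camkii as ck, ecb, membrane as mem
        from striatal_stdp import plasticity as plas
        from striatal_stdp.stimuli import action_current, glutamate_concentration

        proto = build_stdp_protocol(3, -15.0, 1.0, params)
        names = list(STATE_NAMES)
        for _ in range(20):
            y = rest * np.exp(rng.normal(0, 0.1, N_STATE))
            y[names.index("V")] = rest[names.index("V")] + rng.normal(0, 5)
            t = float(rng.uniform(0.9, 3.5))
            dy = full_rhs(t, y, params, proto)

            g = glutamate_concentration(t, proto, params)
            i_act = action_current(t, proto, params)
            ms = mem.MembraneState(*(y[names.index(k)] for k in
                                    ("V", "r_AMPA", "r_NMDA", "m_VSCC", "h_VSCC")))
            aea = y[names.index("AEA")]
            currents = mem.synaptic_and_channel_currents(ms, aea, params)
            assert dy[0] == pytest.approx(mem.membrane_rhs(ms, currents, i_act, params),
                                          rel=1e-12)
            dra, drn = mem.receptor_gating_rhs(ms, g, params)
            assert dy[1] == pytest.approx(dra, rel=1e-12)
            assert dy[2] == pytest.approx(drn, rel=1e-12)

            cs = calc.CalciumState(C=y[names.index("C")], C_ER=y[names.index("C_ER")],
                                   IP3=y[names.index("IP3")], h_IP3R=y[names.index("h_IP3R")])
            dC, dCER = calc.calcium_rhs(cs, currents[1:], params)
            assert dy[names.index("C")] == pytest.approx(dC, rel=1e-9)
            assert dy[names.index("C_ER")] == pytest.approx(dCER, rel=1e-9)

            B = y[names.index("B0"):names.index("B0") + 14]
            frac = ck.camkii_active(B) / params.CaMKII_act_max
            assert dy[names.index("IP3")] == pytest.approx(
                calc.ip3_rhs(cs, g, frac, params), rel=1e-9)

            es = ecb.EcbState(DAG=y[names.index("DAG")], AG2=y[names.index("AG2")],
                              AEA=aea, phi_DAGL=y[names.index("phi_DAGL")],
                              x_CB1R=y[names.index("x_CB1R")],
                              d_CB1R=y[names.index("d_CB1R")])
            rp = calc.ip3_production(g, cs.C, cs.IP3, params)
            dDAG, dAG2 = ecb.dag_and_2ag_rhs(es, rp, params)
            assert dy[names.index("DAG")] == pytest.approx(dDAG, rel=1e-9)
            assert dy[names.index("AG2")] == pytest.approx(dAG2, rel=1e-9)
            assert dy[names.index("AEA")] == pytest.approx(
                ecb.aea_rhs(aea, cs.C, params), rel=1e-9)
            dx, dd = ecb.cb1r_rhs(es, params)
            assert dy[names.index("x_CB1R")] == pytest.approx(dx, rel=1e-9)
            assert dy[names.index("d_CB1R")] == pytest.approx(dd, rel=1e-9)

            st = ck.CamkiiState(B=B, PP1=y[names.index("PP1")], I1P=y[names.index("I1P")])
            dB, dPP1, dI1P = ck.camkii_subsystem_rhs(st, cs.C, params)
            assert np.allclose(dy[names.index("B0"):names.index("B0") + 14], dB,
                               rtol=1e-9, atol=1e-12)
            assert dy[names.index("PP1")] == pytest.approx(dPP1, rel=1e-9)
            assert dy[names.index("I1P")] == pytest.approx(dI1P, rel=1e-9)

            assert dy[names.index("W_pre")] == pytest.approx(
                plas.wpre_rhs(y[names.index("W_pre")], es.x_CB1R, params), rel=1e-9)


class TestRunProtocol:
    def test_bitwise_reproducibility(self, params):
        proto = build_stdp_protocol(3, -15.0, 1.0, params)
        r1 = run_protocol(params, proto, settle_time=20.0)
        r2 = run_protocol(params, proto, settle_time=20.0)
        assert np.array_equal(r1.states, r2.states)
        assert r1.w_total == r2.w_total

    def test_cb1r_conservation_along_trajectory(self, params):
        proto = build_stdp_protocol(20, -15.0, 1.0, params)
        r = run_protocol(params, proto, settle_time=20.0)
        x, d = r.column("x_CB1R"), r.column("d_CB1R")
        assert (x >= -1e-6).all() and (d >= -1e-6).all()
        assert (x + d <= 1.0 + 1e-6).all()

    def test_weight_change_percent_convention(self, params):
        proto = build_stdp_protocol(2, 30.0, 1.0, params)  # weak protocol
        res = run_protocol(params, proto, record=False)
        dpre, dpost, dtot = weight_change(res)
        assert dtot == pytest.approx(100.0 * res.w_total)
        assert dpre == pytest.approx(100.0 * res.w_pre)

    def test_serialization(self, params, tmp_path):
        proto = build_stdp_protocol(2, -15.0, 1.0, params)
        res = run_protocol(params, proto, settle_time=10.0)
        res.to_csv(tmp_path / "traj.csv")
        res.to_json(tmp_path / "scalars.json")
        import json

        import pandas as pd

        df = pd.read_csv(tmp_path / "traj.csv")
        assert list(df.columns) == ["t", *STATE_NAMES]
        blob = json.loads((tmp_path / "scalars.json").read_text())
        assert blob["w_total"] == pytest.approx(res.w_total)
        assert blob["params"]["tau_G"] == params.tau_G
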