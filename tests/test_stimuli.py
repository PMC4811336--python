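"""Protocol construction and analytic forcing terms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from striatal_stdp.stimuli import (
    T_START,
    build_post_only_protocol,
    build_pre_only_protocol,
    build_stdp_protocol,
    action_current,
    glutamate_concentration,
)


class TestProtocolGeometry:
    @pytest.mark.parametrize("dt_ms", [-30.0, -15.0, 0.0, 15.0, 30.0])
    def test_timing_convention(self, params, dt_ms):
        proto = build_stdp_protocol(10, dt_ms, 1.0, params)
        for tp, to in zip(proto.pre_times, proto.post_times):
            assert to + params.delta - tp == pytest.approx(dt_ms * 1e-3)

    def test_negative_dt_means_post_first(self, params):
        proto = build_stdp_protocol(1, -15.0, 1.0, params)
        assert proto.post_times[0] < proto.pre_times[0]

    def test_pairing_period_and_span(self, params):
        proto = build_stdp_protocol(100, 15.0, 1.0, params)
        pre = np.asarray(proto.pre_times)
        assert np.allclose(np.diff(pre), 1.0)
        assert pre[-1] - pre[0] == pytest.approx(99.0)

    def test_dt_too_large_for_period(self, params):
        with pytest.raises(ValueError, match="too large"):
            build_stdp_protocol(10, 300.0, 2.0, params)

    def test_unpaired_protocols(self, params):
        pre = build_pre_only_protocol(5, 1.0)
        assert pre.post_times == () and len(pre.pre_times) == 5
        post = build_post_only_protocol(5, 1.0)
        assert post.pre_times == () and len(post.post_times) == 5


class TestGlutamate:
    def test_peak_and_decay(self, params):
        proto = build_pre_only_protocol(1, 1.0)
        t0 = proto.pre_times[0]
        assert glutamate_concentration(t0, proto, params) == pytest.approx(params.G_max)
        assert glutamate_concentration(t0 + params.tau_G, proto, params) == pytest.approx(
            params.G_max / math.e
        )
        assert glutamate_concentration(t0 - 1e-6, proto, params) == 0.0

    def test_additive_over_spikes(self, params):
        proto = build_pre_only_protocol(1, 1.0)
        two = type(proto)(
            pre_times=(proto.pre_times[0], proto.pre_times[0]),
            post_times=(), dt_stdp=float("nan"), n_pairings=2, frequency=1.0,
            kind="pre-only",
        )
        g1 = glutamate_concentration(proto.pre_times[0], proto, params)
        g2 = glutamate_concentration(proto.pre_times[0], two, params)
        assert g2 == pytest.approx(2.0 * g1)


class TestActionCurrent:
    def test_before_all_events_zero(self, params):
        proto = build_post_only_protocol(3, 1.0)
        assert action_current(proto.post_times[0] - 1e-6, proto, params) == 0.0

    def test_inside_step_is_dc(self, params):
        proto = build_post_only_protocol(1, 1.0)
        t0 = proto.post_times[0]
        t_probe = t0 + params.delta / 2  # inside step, before bAP onset
        assert action_current(t_probe, proto, params) == pytest.approx(-params.DC_max)

    def test_bap_superposition(self, params):
        proto = build_post_only_protocol(1, 1.0)
        t0 = proto.post_times[0]
        assert params.delta < params.DC_dur
        t_probe = t0 + 1.001 * params.delta
        val = action_current(t_probe, proto, params)
        bap = params.AP_max * math.exp(-(t_probe - t0 - params.delta) / params.tau_bAP)
        assert val == pytest.approx(-params.DC_max - bap, rel=1e-9)

    def test_step_ends_after_dc_dur(self, params):
        proto = build_post_only_protocol(1, 1.0)
        t0 = proto.post_times[0]
        val = action_current(t0 + params.DC_dur + 20 * params.tau_bAP, proto, params)
        assert abs(val) < 1e-3 * params.DC_max


class TestTimeInvariance:
    @settings(max_examples=25, deadline=None)
    @given(shift=st.floats(-0.5, 0.5), t_rel=st.floats(-0.1, 0.4))
    def test_shifting_events_shifts_forcing(self, shift, t_rel):
        from striatal_stdp import load_default_parameters

        params = load_default_parameters()
        base = build_stdp_protocol(3, -15.0, 2.0, params)
        moved = type(base)(
            pre_times=tuple(t + shift for t in base.pre_times),
            post_times=tuple(t + shift for t in base.post_times),
            dt_stdp=base.dt_stdp, n_pairings=3, frequency=2.0,
        )
        t = T_START + t_rel
        assert glutamate_concentration(t, base, params) == pytest.approx(
            glutamate_concentration(t + shift, moved, params), rel=1e-9, abs=1e-12
        )
        assert action_current(t, base, params) == pytest.approx(
            action_current(t + shift, moved, params), rel=1e-9, abs=1e-12
        )
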