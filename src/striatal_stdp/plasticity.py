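"""Presynaptic plasticity rule and weight composition.

The presynaptic weight W_pre relaxes toward a target Omega(y_CB1R) set by
the CB1R activation drive y_CB1R = k_CB1R * x_CB1R + D_1: no change below
theta_LTD_start or in the dead zone between theta_LTD_stop and
theta_LTP_start, depression (1 - A_LTD) inside the LTD band, potentiation
(1 + A_LTP) above the LTP threshold.  The relaxation time constant
tau_Wpre(k_CB1R * x_CB1R + D_2) is fast at high drive and extremely slow at
rest, which freezes the weight after the protocol (memory).  The total
weight is the product W_total = W_pre * W_post.
"""

from __future__ import annotations

from math import exp

from .parameters import ParameterSet

__all__ = [
    "drive",
    "omega",
    "omega_smooth",
    "tau_wpre",
    "wpre_rhs",
    "total_weight",
]


def drive(x_cb1r: float, params: ParameterSet) -> float:
    """CB1R activation drive y_CB1R = k_CB1R * x_CB1R + D_1."""
    return params.k_CB1R * x_cb1r + params.D_1


def omega(y: float, params: ParameterSet) -> float:
    """Sharp three-branch target: 1, 1 - A_LTD, or 1 + A_LTP."""
    if params.theta_LTD_start <= y <= params.theta_LTD_stop:
        return 1.0 - params.A_LTD
    if y > params.theta_LTP_start:
        return 1.0 + params.A_LTP
    return 1.0


def _sigma(u: float) -> float:
    # overflow-safe logistic
    if u >= 0:
        return 1.0 / (1.0 + exp(-u))
    z = exp(u)
    return z / (1.0 + z)


def omega_smooth(y: float, k_s: float, params: ParameterSet) -> float:
    """Smooth sigmoidal version of the threshold rule.

    Logistic steps replace the sharp branch boundaries; the steepness unit
    is half the LTD band width, so the rule converges pointwise to the sharp
    one (off the thresholds) as ``k_s`` grows.  ``k_s = 2`` is the default
    mild smoothing.
    """
    if k_s <= 0:
        raise ValueError("k_s must be positive")
    w = 0.5 * (params.theta_LTD_stop - params.theta_LTD_start)
    s = k_s / w * 10.0
    ltd = _sigma(s * (y - params.theta_LTD_start)) * _sigma(s * (params.theta_LTD_stop - y))
    ltp = _sigma(s * (y - params.theta_LTP_start))
    return 1.0 - params.A_LTD * ltd + params.A_LTP * ltp


def tau_wpre(x: float, params: ParameterSet) -> float:
    """State-dependent relaxation time tau(x) = P_1/(P_2^P_3 + x^P_3) + P_4 (s)."""
    return params.P_1 / (params.P_2**params.P_3 + x**params.P_3) + params.P_4


def wpre_rhs(w_pre: float, x_cb1r: float, params: ParameterSet) -> float:
    """dW_pre/dt with the ceiling implemented as derivative truncation."""
    y = drive(x_cb1r, params)
    if params.use_smooth_omega:
        target = omega_smooth(y, params.k_S, params)
    else:
        target = omega(y, params)
    tau = tau_wpre(params.k_CB1R * x_cb1r + params.D_2, params)
    dw = (target - w_pre) / tau
    if w_pre >= params.W_pre_max and dw > 0.0:
        return 0.0
    return dw


def total_weight(w_pre: float, w_post: float) -> float:
    """W_total = W_pre * W_post (1.0 means no plasticity)."""
    return w_pre * w_post
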