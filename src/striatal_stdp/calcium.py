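"""Cytosolic and ER calcium with CICR, rapid buffering, and IP3 dynamics.

Calcium exchanges with the endoplasmic reticulum through an IP3-receptor
channel (Li-Rinzel-type gating with a slow inactivation gate), a Hill-type
SERCA pump, and a passive leak.  Fast endogenous buffering enters as a
quasi-equilibrium time-scaling factor on both compartments.  IP3 is produced
by glutamate/mGluR-activated PLCbeta (with calcium as a cofactor, making
PLCbeta a coincidence detector of presynaptic glutamate and postsynaptic
calcium) and by calcium-activated PLCdelta, and is degraded by IP-5P and by
CaMKII-dependent IP3K.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import ParameterSet

__all__ = [
    "CalciumState",
    "buffer_factor",
    "ip3r_open_fraction",
    "ip3r_gate_rhs",
    "cicr_fluxes",
    "plc_beta_rate",
    "plc_delta_rate",
    "ip3_production",
    "ip3_rhs",
    "calcium_rhs",
]


@dataclass
class CalciumState:
    C: float  # cytosolic free calcium (uM)
    C_ER: float  # ER free calcium (uM)
    IP3: float  # uM
    h_IP3R: float  # IP3R inactivation gate (0..1)


def buffer_factor(x: float, params: ParameterSet) -> float:
    """Rapid-buffer time-scaling factor T(x) = 1 + B_T K_dB / (K_dB + x)^2."""
    return 1.0 + params.B_T * params.K_dB / (params.K_dB + x) ** 2


def ip3r_open_fraction(C: float, IP3: float, h: float, params: ParameterSet) -> float:
    """Open fraction of the IP3R channel, m_inf^3 h^3 (Li-Rinzel gating)."""
    m_inf = (IP3 / (IP3 + params.d_1)) * (C / (C + params.d_5))
    return m_inf**3 * h**3


def ip3r_gate_rhs(state: CalciumState, params: ParameterSet) -> float:
    """Slow calcium-inactivation gate of the IP3R."""
    q2 = params.d_2 * (state.IP3 + params.d_1) / (state.IP3 + params.d_3)
    return params.a_2 * (q2 * (1.0 - state.h_IP3R) - state.C * state.h_IP3R)


def cicr_fluxes(state: CalciumState, params: ParameterSet):
    """Return (J_IP3R, J_SERCA, J_leak) in uM/s (cytosolic volume units)."""
    grad = state.C_ER - state.C
    j_ip3r = params.r_C * ip3r_open_fraction(state.C, state.IP3, state.h_IP3R, params) * grad
    j_serca = params.v_ER * state.C**2 / (state.C**2 + params.K_ER**2)
    j_leak = params.r_L * grad
    return j_ip3r, j_serca, j_leak


def plc_beta_rate(G: float, C: float, params: ParameterSet) -> float:
    """mGluR/PLCbeta production rate: requires glutamate AND calcium."""
    gn = G**params.n_G
    cn = C**params.n_pi
    return params.v_beta * gn / (gn + params.K_R**params.n_G) * cn / (cn + params.K_pi**params.n_pi)


def plc_delta_rate(C: float, IP3: float, params: ParameterSet) -> float:
    """PLCdelta production rate: calcium-activated, product-inhibited."""
    return (
        params.v_delta
        / (1.0 + IP3 / params.kappa_delta)
        * C**2
        / (C**2 + params.K_PLCdelta**2)
    )


def ip3_production(G: float, C: float, IP3: float, params: ParameterSet) -> float:
    """R_P(C, IP3, G): total PLC production rate (shared by IP3 and DAG)."""
    return plc_beta_rate(G, C, params) + plc_delta_rate(C, IP3, params)


def ip3_rhs(state: CalciumState, G: float, camkii_fraction: float, params: ParameterSet) -> float:
    """dIP3/dt.

    Degradation combines linear IP-5P and IP3K; IP3K activity follows the
    phosphorylated-CaMKII fraction supplied by the CaMKII subsystem (not a
    Hill proxy of calcium).
    """
    prod = ip3_production(G, state.C, state.IP3, params)
    j_5p = params.r_5P * state.IP3
    j_3k = params.v_3K * camkii_fraction * state.IP3 / (state.IP3 + params.K_3)
    return prod - j_5p - j_3k


def calcium_rhs(state: CalciumState, currents, params: ParameterSet):
    """(dC/dt, dC_ER/dt) given channel calcium currents (I_NMDA, I_VSCC, I_TRPV1)."""
    i_nmda, i_vscc, i_trpv1 = currents
    j_ip3r, j_serca, j_leak = cicr_fluxes(state, params)
    net_cicr = j_ip3r - j_serca + j_leak
    influx = (
        -params.xi_NMDA * i_nmda - params.xi_VSCC * i_vscc - params.xi_TRPV1 * i_trpv1
    )
    dC = (net_cicr - (state.C - params.Ca_b) / params.tau_Cab + influx) / buffer_factor(
        state.C, params
    )
    dC_ER = -params.rho_ER * net_cicr / buffer_factor(state.C_ER, params)
    return dC, dC_ER
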