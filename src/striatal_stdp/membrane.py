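"""Postsynaptic membrane: isopotential compartment and channel currents.

The compartment carries AMPAR and NMDAR (two-state transmitter-binding
kinetics with a voltage-dependent magnesium block at 1 mM Mg2+), an L-type
Cav1.3 VSCC with Hodgkin-Huxley-type activation/inactivation, and a TRPV1
channel gated by voltage and anandamide.  The bAP is imposed through the
action current, not generated.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp

from .parameters import ParameterSet

__all__ = [
    "MembraneState",
    "receptor_gating_rhs",
    "mg_block",
    "vscc_gating_inf",
    "trpv1_open_probability",
    "synaptic_and_channel_currents",
    "membrane_rhs",
]


@dataclass
class MembraneState:
    V: float  # mV
    r_AMPA: float  # bound-receptor fraction
    r_NMDA: float
    m_VSCC: float  # Cav1.3 activation gate
    h_VSCC: float  # Cav1.3 inactivation gate


def receptor_gating_rhs(state: MembraneState, G: float, params: ParameterSet):
    """Two-state (closed <-> open) receptor kinetics driven by glutamate.

    dr/dt = alpha * G * (1 - r) - beta * r for each receptor class.
    """
    dr_ampa = params.alpha_AMPA * G * (1.0 - state.r_AMPA) - params.beta_AMPA * state.r_AMPA
    dr_nmda = params.alpha_NMDA * G * (1.0 - state.r_NMDA) - params.beta_NMDA * state.r_NMDA
    return dr_ampa, dr_nmda


def mg_block(V: float, params: ParameterSet) -> float:
    """Voltage-dependent magnesium block factor of the NMDAR (0..1)."""
    return 1.0 / (1.0 + exp(-params.Mg_slope * V) * params.Mg_out / params.Mg_K)


def vscc_gating_inf(V: float, params: ParameterSet):
    """Steady-state Cav1.3 activation and inactivation."""
    m_inf = 1.0 / (1.0 + exp(-(V - params.V_m_half) / params.k_m_VSCC))
    h_inf = 1.0 / (1.0 + exp((V - params.V_h_half) / params.k_h_VSCC))
    return m_inf, h_inf


def trpv1_open_probability(V: float, AEA: float, params: ParameterSet) -> float:
    """TRPV1 open probability: voltage-gated, with AEA shifting the half voltage.

    A two-state voltage sensor whose half-activation voltage is pulled toward
    hyperpolarized values by agonist binding; increasing AEA monotonically
    increases the open probability at fixed V.
    """
    shift = params.dV_TRPV1 * AEA / (AEA + params.K_AEA_TRPV1)
    v_half = params.V_TRPV1_half - shift
    return 1.0 / (1.0 + exp(-(V - v_half) / params.k_TRPV1))


def synaptic_and_channel_currents(state: MembraneState, AEA: float, params: ParameterSet):
    """Return (I_AMPA, I_NMDA, I_VSCC, I_TRPV1) in pA (inward negative)."""
    V = state.V
    i_ampa = params.g_AMPA * state.r_AMPA * (V - params.E_glu)
    i_nmda = params.g_NMDA * state.r_NMDA * mg_block(V, params) * (V - params.E_glu)
    i_vscc = params.g_VSCC * state.m_VSCC * state.h_VSCC * (V - params.E_Ca)
    i_trpv1 = params.g_TRPV1 * V * trpv1_open_probability(V, AEA, params)
    return i_ampa, i_nmda, i_vscc, i_trpv1


def membrane_rhs(state: MembraneState, currents, I_act: float, params: ParameterSet) -> float:
    """dV/dt (mV/s) of the isopotential compartment."""
    i_ampa, i_nmda, i_vscc, i_trpv1 = currents
    return (
        -params.g_L * (state.V - params.V_L) - i_ampa - i_nmda - i_vscc - i_trpv1 - I_act
    ) / params.C_m
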