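"""Endocannabinoid cascade: DAG -> 2-AG, NAPE-pathway AEA, and CB1R kinetics.

2-AG is produced postsynaptically by calcium-activated DAGLalpha from DAG
(itself co-produced with IP3 by PLC) and degraded presynaptically by
MAG-lipase (the rate constant lumps degradation and spillover).  AEA follows
a quasi-steady-state reduction of the two-step NAPE pathway.  CB1R is a
closed three-state kinetic scheme (open x, desensitized d, inactivated i
with x + d + i = 1) driven by eCB = 2-AG + 0.10 AEA (AEA is a partial
agonist).
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import ParameterSet

__all__ = [
    "EcbState",
    "dagl_activation_rhs",
    "dagl_flux",
    "dag_and_2ag_rhs",
    "aea_rhs",
    "ecb_concentration",
    "cb1r_rhs",
]


@dataclass
class EcbState:
    DAG: float  # uM
    AG2: float  # 2-arachidonoylglycerol, uM
    AEA: float  # anandamide, uM
    phi_DAGL: float  # activated DAGLalpha fraction (0..1)
    x_CB1R: float  # open CB1R fraction
    d_CB1R: float  # desensitized CB1R fraction

    @property
    def i_CB1R(self) -> float:
        return 1.0 - self.x_CB1R - self.d_CB1R


def dagl_activation_rhs(phi: float, C: float, params: ParameterSet) -> float:
    """Calcium-activation of DAGLalpha: dphi/dt = r_k C^n_c (1 - phi) - r_p phi."""
    return params.r_k * C**params.n_c * (1.0 - phi) - params.r_p * phi


def dagl_flux(DAG: float, phi: float, params: ParameterSet) -> float:
    """DAGLalpha 2-AG synthesis flux (Michaelis-Menten in DAG), uM/s."""
    return params.r_DGL * params.DAGL_T * phi * DAG / (DAG + params.K_DAGL)


def dag_and_2ag_rhs(state: EcbState, R_P: float, params: ParameterSet):
    """(dDAG/dt, d2AG/dt); the DAGLalpha flux appears with opposite signs."""
    flux = dagl_flux(state.DAG, state.phi_DAGL, params)
    dDAG = R_P - flux - params.r_DAGK * state.DAG
    dAG2 = flux - params.r_MAGL * state.AG2
    return dDAG, dAG2


def aea_rhs(AEA: float, C: float, params: ParameterSet) -> float:
    """dAEA/dt = nu_AT C - r_FAAH AEA / (K_FAAH + AEA)."""
    return params.nu_AT * C - params.r_FAAH * AEA / (params.K_FAAH + AEA)


def ecb_concentration(AG2: float, AEA: float, params: ParameterSet) -> float:
    """Effective CB1R agonist concentration, eCB = 2-AG + A_AEA * AEA."""
    return AG2 + params.A_AEA * AEA


def cb1r_rhs(state: EcbState, params: ParameterSet):
    """(dx/dt, dd/dt) of the three-state CB1R scheme; i = 1 - x - d."""
    ecb = ecb_concentration(state.AG2, state.AEA, params)
    i = 1.0 - state.x_CB1R - state.d_CB1R
    dx = params.alpha_CB1R * ecb * i - (params.beta_CB1R + params.gamma_CB1R) * state.x_CB1R
    dd = -params.epsilon_CB1R * state.d_CB1R + params.gamma_CB1R * state.x_CB1R
    return dx, dd
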