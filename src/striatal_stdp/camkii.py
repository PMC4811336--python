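"""Bistable CaMKII switch: calmodulin -> PKA/CaN -> I1/PP1 -> CaMKII.

The CaMKII holoenzyme is a ring of six subunits.  A subunit is
phosphorylated either by *initiation* (it and its counter-clockwise
neighbor both carry (Ca)4-calmodulin; rate ``k_6 * gamma^2``) or by
*propagation* (its counter-clockwise neighbor is already phosphorylated and
the subunit itself carries (Ca)4CaM; rate ``k_7 * gamma``), where ``gamma``
is the probability that a subunit binds (Ca)4CaM.  Dephosphorylation is by
PP1 acting on the common pool of phosphorylated subunits (Michaelis-Menten
with constant K_M).  PP1 is inhibited by phosphorylated inhibitor-1, whose
phosphorylation balance is set by calcium-activated PKA (Hill exponent
``n_PKA``, 3 by default) and calcineurin.

Ring configurations are grouped into the 14 rotation-equivalence classes
B0..B13; the class-to-class transition matrices are generated by direct
enumeration of the 64 configurations, which avoids hand-transcription
errors in the combinatorial coefficients.

At basal calcium the subsystem is bistable: a down state with essentially
no phosphorylated CaMKII and an up state near saturation.  The postsynaptic
weight is a linear readout of the phosphorylated-subunit concentration.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from .parameters import ParameterSet

__all__ = [
    "N_CLASSES",
    "CLASS_NPHOS",
    "CamkiiState",
    "ring_classes",
    "transition_matrices",
    "cam_ca4",
    "cam_binding_probability",
    "pka_activity",
    "can_activity",
    "camkii_subsystem_rhs",
    "camkii_active",
    "find_bistable_states",
    "w_post",
]

N_SUBUNITS = 6


def _canon(cfg: int) -> int:
    """Canonical representative of the rotation orbit of a 6-bit ring."""
    best = cfg
    for _ in range(N_SUBUNITS - 1):
        cfg = ((cfg >> 1) | ((cfg & 1) << (N_SUBUNITS - 1))) & 0x3F
        best = min(best, cfg)
    return best


@lru_cache(maxsize=1)
def ring_classes():
    """Rotation classes of the 6-subunit ring.

    Returns (class_of_config, representatives, n_phospho) with classes
    sorted by (number of phosphorylated subunits, canonical bit pattern),
    so class 0 is the fully unphosphorylated ring and class 13 the fully
    phosphorylated one.
    """
    reps = sorted({_canon(c) for c in range(64)}, key=lambda c: (bin(c).count("1"), c))
    index = {rep: k for k, rep in enumerate(reps)}
    class_of = np.array([index[_canon(c)] for c in range(64)], dtype=int)
    nphos = np.array([bin(rep).count("1") for rep in reps], dtype=float)
    return class_of, np.array(reps, dtype=int), nphos


_CLASS_OF, _REPS, CLASS_NPHOS = ring_classes()
N_CLASSES = len(_REPS)  # 14


@lru_cache(maxsize=1)
def transition_matrices():
    """Class-level generator matrices (A_init, A_prop, A_deph).

    dB/dt = (k6 g^2 A_init + k7 g A_prop + u A_deph) @ B, with u the
    per-subunit PP1 dephosphorylation rate.  Columns sum to zero, so the
    total holoenzyme concentration is conserved exactly.
    """
    class_of = _CLASS_OF
    a_init = np.zeros((N_CLASSES, N_CLASSES))
    a_prop = np.zeros((N_CLASSES, N_CLASSES))
    a_deph = np.zeros((N_CLASSES, N_CLASSES))
    for k, rep in enumerate(_REPS):
        bits = [(rep >> i) & 1 for i in range(N_SUBUNITS)]
        for i in range(N_SUBUNITS):
            j = (i + 1) % N_SUBUNITS  # clockwise neighbor of i
            if bits[j] == 0:
                tgt = class_of[rep | (1 << j)]
                if bits[i] == 0:  # initiation: both subunits need CaM
                    a_init[tgt, k] += 1.0
                    a_init[k, k] -= 1.0
                else:  # propagation: only the substrate needs CaM
                    a_prop[tgt, k] += 1.0
                    a_prop[k, k] -= 1.0
            if bits[i] == 1:  # dephosphorylation of subunit i
                tgt = class_of[rep & ~(1 << i)]
                a_deph[tgt, k] += 1.0
                a_deph[k, k] -= 1.0
    return a_init, a_prop, a_deph


@dataclass
class CamkiiState:
    B: np.ndarray  # holoenzyme concentration per ring class, length 14 (uM)
    PP1: float  # free active PP1 (uM)
    I1P: float  # phosphorylated inhibitor-1 (uM)


def cam_ca4(C: float, params: ParameterSet) -> float:
    """(Ca)4CaM concentration from sequential 4-site equilibrium binding."""
    if C <= 0.0:
        return 0.0
    k4, k3, k2, k1 = params.K_CaM4, params.K_CaM3, params.K_CaM2, params.K_CaM1
    denom = 1.0 + k4 / C * (1.0 + k3 / C * (1.0 + k2 / C * (1.0 + k1 / C)))
    return params.CaM_T / denom


def cam_binding_probability(C: float, params: ParameterSet) -> float:
    """Probability gamma that a CaMKII subunit carries (Ca)4CaM."""
    m = cam_ca4(C, params)
    return m / (params.K_5 + m)


def pka_activity(C: float, params: ParameterSet) -> float:
    """I1 phosphorylation rate by PKA (effective calcium activation, Hill n_PKA)."""
    cn = C**params.n_PKA
    return params.k_PKA0 + params.k_PKA * cn / (cn + params.K_PKA**params.n_PKA)


def can_activity(C: float, params: ParameterSet) -> float:
    """I1p dephosphorylation rate by calcineurin (Hill n_CaN)."""
    cn = C**params.n_CaN
    return params.k_CaN0 + params.k_CaN * cn / (cn + params.K_CaN**params.n_CaN)


def camkii_active(B: np.ndarray) -> float:
    """Concentration of phosphorylated subunits (uM)."""
    return float(CLASS_NPHOS @ B)


def camkii_subsystem_rhs(state: CamkiiState, C: float, params: ParameterSet):
    """(dB/dt, dPP1/dt, dI1P/dt) at cytosolic calcium C."""
    a_init, a_prop, a_deph = transition_matrices()
    g = cam_binding_probability(C, params)
    s_act = camkii_active(state.B)
    u = params.k_12 * state.PP1 / (params.K_M + s_act)
    gen = (params.k_6 * g * g) * a_init + (params.k_7 * g) * a_prop + u * a_deph
    dB = gen @ state.B
    complex_ = params.PP1_T - state.PP1  # PP1:I1p complex
    i1_free = max(params.I1_T - state.I1P - complex_, 0.0)
    bind = params.k_11 * state.I1P * state.PP1 - params.km_11 * complex_
    dPP1 = -bind
    dI1P = pka_activity(C, params) * i1_free - can_activity(C, params) * state.I1P - bind
    return dB, dPP1, dI1P


def w_post(camkii_act: float, params: ParameterSet) -> float:
    """Postsynaptic weight: W_post = 1 + gain * CaMKII_act / CaMKII_act_max."""
    amax = params.CaMKII_act_max
    if camkii_act < -1e-9 or camkii_act > amax * (1.0 + 1e-9):
        raise ValueError(f"CaMKII_act = {camkii_act} outside [0, {amax}]")
    frac = min(max(camkii_act / amax, 0.0), 1.0) if amax > 0 else 0.0
    return 1.0 + params.w_post_gain * frac


# ---------------------------------------------------------------------------
# fixed points at clamped calcium


def _equilibrium_state(C: float, s_target: float, params: ParameterSet):
    """PP1/I1P equilibrium at clamped C, and the B distribution consistent
    with a given total phosphorylated-subunit concentration (used only to
    seed relaxation)."""
    vp = pka_activity(C, params)
    vc = can_activity(C, params)

    def i1p_residual(i1p):
        # complex from PP1 binding equilibrium: k11 * I1P * PP1 = km11 * complex
        # PP1 = PP1_T - complex
        cplx = params.k_11 * i1p * params.PP1_T / (params.km_11 + params.k_11 * i1p)
        i1_free = max(params.I1_T - i1p - cplx, 0.0)
        return vp * i1_free - vc * i1p

    hi = params.I1_T
    i1p = brentq(i1p_residual, 0.0, hi, xtol=1e-12)
    cplx = params.k_11 * i1p * params.PP1_T / (params.km_11 + params.k_11 * i1p)
    return max(params.PP1_T - cplx, 1e-12), i1p


def _relax_B(C: float, B0: np.ndarray, pp1: float, params: ParameterSet, t_max=2e5):
    """Integrate the B subsystem at clamped C and PP1 to a fixed point."""
    from scipy.integrate import solve_ivp

    a_init, a_prop, a_deph = transition_matrices()
    g = cam_binding_probability(C, params)

    def rhs(_t, B):
        s_act = CLASS_NPHOS @ B
        u = params.k_12 * pp1 / (params.K_M + s_act)
        gen = (params.k_6 * g * g) * a_init + (params.k_7 * g) * a_prop + u * a_deph
        return gen @ B

    sol = solve_ivp(rhs, (0.0, t_max), B0, method="LSODA", rtol=1e-12, atol=1e-14)
    if not sol.success:
        raise RuntimeError(f"CaMKII relaxation failed: {sol.message}")
    B = sol.y[:, -1]
    d = np.abs(rhs(0.0, B)).max()
    if d > 1e-6 * max(params.CaMKII_T, 1e-12):
        raise RuntimeError(f"CaMKII relaxation did not converge (max |dB/dt| = {d:g})")
    return B


def find_bistable_states(params: ParameterSet, C: float):
    """Stable fixed points of the subsystem at clamped calcium C.

    Returns (down_state, up_state, bistable_flag) where each state is a
    CamkiiState; if the subsystem is monostable at C both entries hold the
    single attractor and the flag is False.
    """
    pp1, i1p = _equilibrium_state(C, 0.0, params)
    down0 = np.zeros(N_CLASSES)
    down0[0] = params.CaMKII_T
    up0 = np.zeros(N_CLASSES)
    up0[-1] = params.CaMKII_T
    b_down = _relax_B(C, down0, pp1, params)
    b_up = _relax_B(C, up0, pp1, params)
    s_down, s_up = camkii_active(b_down), camkii_active(b_up)
    bistable = abs(s_up - s_down) > 0.05 * params.CaMKII_act_max
    down = CamkiiState(B=b_down, PP1=pp1, I1P=i1p)
    up = CamkiiState(B=b_up, PP1=pp1, I1P=i1p)
    return down, up, bool(bistable)
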