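"""Stimulation protocols and their forcing terms.

A protocol is a pair of event trains: presynaptic spikes (cortical
stimulation, releasing cleft glutamate) and postsynaptic step onsets
(somatic depolarizing current steps, each evoking one bAP after a delay
``delta``).  The spike-timing convention is

    dt_STDP = t_post_i + delta - t_pre_i

so ``dt_STDP < 0`` means the postsynaptic spike (bAP peak) precedes the
presynaptic one (post-pre pairing), and ``dt_STDP > 0`` pre-post.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from math import exp

import numpy as np

from .parameters import ParameterSet

__all__ = [
    "ProtocolSpec",
    "build_stdp_protocol",
    "build_pre_only_protocol",
    "build_post_only_protocol",
    "glutamate_concentration",
    "action_current",
]

#: protocols start at this offset so that forcing history is trivially empty
T_START = 1.0


@dataclass(frozen=True)
class ProtocolSpec:
    """Timed pre/postsynaptic stimulation events."""

    pre_times: tuple[float, ...]
    post_times: tuple[float, ...]
    dt_stdp: float  # ms (signed; NaN for unpaired protocols)
    n_pairings: int
    frequency: float  # Hz
    kind: str = "paired"  # paired | pre-only | post-only

    def __post_init__(self):
        if self.kind not in ("paired", "pre-only", "post-only"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.kind == "paired" and len(self.pre_times) != len(self.post_times):
            raise ValueError("paired protocols need equal numbers of pre and post events")

    @property
    def end_time(self) -> float:
        """Time of the last stimulation event."""
        last = 0.0
        if self.pre_times:
            last = max(last, self.pre_times[-1])
        if self.post_times:
            last = max(last, self.post_times[-1])
        return last

    def event_times(self, params: ParameterSet) -> np.ndarray:
        """All forcing discontinuities (integrator restart points)."""
        ts: list[float] = list(self.pre_times)
        for tp in self.post_times:
            ts += [tp, tp + params.delta, tp + params.DC_dur]
        return np.unique(np.asarray(ts, dtype=float))


def build_stdp_protocol(
    n_pairings: int,
    dt_stdp_ms: float,
    frequency: float,
    params: ParameterSet,
) -> ProtocolSpec:
    """Build a paired STDP protocol.

    ``dt_stdp_ms`` is the spike timing in milliseconds; pairings repeat at
    ``frequency`` Hz.  Events are placed so that
    ``t_post_i + delta - t_pre_i = dt_stdp`` for every pairing.
    """
    if n_pairings < 1:
        raise ValueError("n_pairings must be >= 1")
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    dt = dt_stdp_ms * 1e-3
    period = 1.0 / frequency
    if abs(dt) >= period / 2:
        raise ValueError(
            f"|dt_STDP| = {abs(dt_stdp_ms)} ms is too large for pairing period {period * 1e3:g} ms"
        )
    pre = T_START + period * np.arange(n_pairings)
    post = pre + dt - params.delta
    return ProtocolSpec(
        pre_times=tuple(pre),
        post_times=tuple(post),
        dt_stdp=float(dt_stdp_ms),
        n_pairings=int(n_pairings),
        frequency=float(frequency),
        kind="paired",
    )


def build_pre_only_protocol(n_stim: int, frequency: float) -> ProtocolSpec:
    """Presynaptic-only stimulation train (no postsynaptic steps)."""
    if n_stim < 1:
        raise ValueError("n_stim must be >= 1")
    pre = T_START + np.arange(n_stim) / frequency
    return ProtocolSpec(
        pre_times=tuple(pre),
        post_times=(),
        dt_stdp=float("nan"),
        n_pairings=int(n_stim),
        frequency=float(frequency),
        kind="pre-only",
    )


def build_post_only_protocol(n_stim: int, frequency: float) -> ProtocolSpec:
    """Postsynaptic-only stimulation train (no presynaptic spikes)."""
    if n_stim < 1:
        raise ValueError("n_stim must be >= 1")
    post = T_START + np.arange(n_stim) / frequency
    return ProtocolSpec(
        pre_times=(),
        post_times=tuple(post),
        dt_stdp=float("nan"),
        n_pairings=int(n_stim),
        frequency=float(frequency),
        kind="post-only",
    )


def glutamate_concentration(t: float, protocol: ProtocolSpec, params: ParameterSet) -> float:
    """Cleft glutamate: a decaying exponential per presynaptic spike.

    G(t) = G_max * sum_i exp(-(t - t_pre_i)/tau_G) * H(t - t_pre_i);
    contributions are additive over spikes.
    """
    pre = protocol.pre_times
    tau = params.tau_G
    g = 0.0
    # spikes older than ~40 tau contribute < 5e-18 G_max: skip them
    i_hi = bisect_right(pre, t)
    i_lo = bisect_right(pre, t - 40.0 * tau)
    for i in range(i_lo, i_hi):
        g += exp(-(t - pre[i]) / tau)
    return params.G_max * g


def action_current(t: float, protocol: ProtocolSpec, params: ParameterSet) -> float:
    """Postsynaptic action current: step depolarization plus delayed bAP transient.

    I_act(t) = -DC_max * sum_i box(t; t_post_i, DC_dur)
               -AP_max * sum_i H(t - delta - t_post_i) exp(-(t - delta - t_post_i)/tau_bAP)

    Negative amplitudes depolarize (inward current convention of the
    membrane equation).
    """
    post = protocol.post_times
    if not post:
        return 0.0
    i_act = 0.0
    # DC window
    i_hi = bisect_right(post, t)
    i_lo = bisect_right(post, t - params.DC_dur)
    i_act -= params.DC_max * (i_hi - i_lo)
    # bAP transients
    tb = t - params.delta
    j_hi = bisect_right(post, tb)
    j_lo = bisect_right(post, tb - 40.0 * params.tau_bAP)
    for j in range(j_lo, j_hi):
        i_act -= params.AP_max * exp(-(tb - post[j]) / params.tau_bAP)
    return i_act
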