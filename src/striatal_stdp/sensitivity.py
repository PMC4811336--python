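"""Monte-Carlo standardized-regression-coefficient (SRC) sensitivity analysis.

Free parameters are sampled independently and uniformly on
[0.1, 1.9] x reference value (variance 0.27 p_ref^2).  For each sampled
vector the model's (dt_STDP, N_pairings) weight map is compared to the
reference map through the root-mean-square distance D over the grid, and D
is regressed linearly on the parameter vector by ordinary least squares.
The standardized coefficient SRC_k = b_k sqrt(Var(p_k)/Var(D)) ranks the
parameters by influence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .engine import run_protocol
from .parameters import PARAM_SPECS, ParameterSet
from .stimuli import build_stdp_protocol

__all__ = [
    "SensitivityReport",
    "DEFAULT_FREE_PARAMETERS",
    "sample_parameter_vectors",
    "map_distance",
    "compute_src",
    "run_sensitivity",
]

#: parameters treated as "free" (not pinned by direct measurements); the
#: set is user-overridable in run_sensitivity.
DEFAULT_FREE_PARAMETERS: tuple[str, ...] = (
    "CaM_T", "CaMKII_T", "B_T", "g_TRPV1", "g_NMDA", "g_VSCC",
    "r_DGL", "r_FAAH", "r_MAGL", "r_DAGK", "gamma_CB1R", "epsilon_CB1R",
    "theta_LTP_start", "tau_G", "v_beta", "r_k", "r_p", "nu_AT",
    "k_CB1R", "alpha_CB1R", "xi_NMDA", "xi_VSCC", "xi_TRPV1", "v_ER",
)

_LOW, _HIGH = 0.1, 1.9  # uniform sampling range, x reference value


@dataclass
class SensitivityReport:
    parameters: list[str]
    src: np.ndarray
    coefficients: np.ndarray
    intercept: float
    ranks: np.ndarray  # rank 1 = largest |SRC|
    n_samples: int
    n_rejected: int
    seed: Optional[int]
    degenerate: bool = False

    def ranked(self) -> list[tuple[str, float]]:
        order = np.argsort(-np.abs(self.src))
        return [(self.parameters[i], float(self.src[i])) for i in order]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "parameter": self.parameters,
                "b": self.coefficients,
                "SRC": self.src,
                "rank": self.ranks,
            }
        ).sort_values("rank")


def sample_parameter_vectors(
    params: ParameterSet,
    free_list: Sequence[str],
    n: int,
    seed: Optional[int],
) -> np.ndarray:
    """Sample n parameter vectors, each component uniform on [0.1, 1.9] p_ref."""
    if n < 1:
        raise ValueError("n must be >= 1")
    unknown = [name for name in free_list if name not in PARAM_SPECS]
    if unknown:
        raise ValueError(f"unknown parameter(s): {', '.join(unknown)}")
    ref = np.array([params[name] for name in free_list])
    rng = np.random.default_rng(seed)
    return rng.uniform(_LOW, _HIGH, size=(n, len(free_list))) * ref


def map_distance(
    candidate: Sequence[float],
    reference: ParameterSet,
    grid: Sequence[tuple[float, int]],
    free_list: Sequence[str],
    frequency: float = 1.0,
    ref_weights: Optional[np.ndarray] = None,
) -> float:
    """RMS weight-map distance between a candidate parameter vector and the reference.

    D = sqrt(mean_i[(W_pre(i|p) - W_pre(i|ref))^2 + (W_post(i|p) - W_post(i|ref))^2])
    over the (dt, N) grid points.  Integration failures raise; callers flag
    and drop such samples rather than imputing them.
    """
    if len(grid) == 0:
        raise ValueError("grid must be non-empty")
    cand = reference.replace(**dict(zip(free_list, map(float, candidate))))
    if ref_weights is None:
        ref_weights = _grid_weights(reference, grid, frequency)
    cw = _grid_weights(cand, grid, frequency)
    return float(np.sqrt(np.mean(np.sum((cw - ref_weights) ** 2, axis=1))))


def _grid_weights(params: ParameterSet, grid, frequency: float) -> np.ndarray:
    out = np.empty((len(grid), 2))
    for i, (dt, n) in enumerate(grid):
        proto = build_stdp_protocol(int(n), float(dt), frequency, params)
        res = run_protocol(params, proto, record=False)
        out[i] = (res.w_pre, res.w_post)
    return out


def compute_src(
    samples: np.ndarray,
    distances: np.ndarray,
    variances: np.ndarray,
    parameters: Sequence[str],
    seed: Optional[int] = None,
    n_rejected: int = 0,
) -> SensitivityReport:
    """Ordinary-least-squares fit of D on p and standardized coefficients."""
    import statsmodels.api as sm

    samples = np.asarray(samples, dtype=float)
    distances = np.asarray(distances, dtype=float)
    n, m = samples.shape
    if n < 2 * m:
        raise ValueError(f"need >= {2 * m} valid samples for {m} free parameters, got {n}")
    var_d = float(np.var(distances))
    # relative threshold: np.var of a constant array returns rounding noise,
    # not an exact zero
    if var_d <= 1e-18 * (1.0 + float(np.mean(distances)) ** 2):
        import warnings

        warnings.warn("distance is constant across samples; SRC is degenerate (all zero)")
        src = np.zeros(m)
        return SensitivityReport(
            parameters=list(parameters),
            src=src,
            coefficients=np.zeros(m),
            intercept=float(distances.mean()) if n else 0.0,
            ranks=np.arange(1, m + 1),
            n_samples=n,
            n_rejected=n_rejected,
            seed=seed,
            degenerate=True,
        )
    design = sm.add_constant(samples)
    fit = sm.OLS(distances, design).fit()
    if np.linalg.matrix_rank(design) < m + 1:
        raise ValueError("rank-deficient regression design")
    b0 = float(fit.params[0])
    b = np.asarray(fit.params[1:])
    src = b * np.sqrt(np.asarray(variances, dtype=float) / var_d)
    order = np.argsort(-np.abs(src))
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    return SensitivityReport(
        parameters=list(parameters),
        src=src,
        coefficients=b,
        intercept=b0,
        ranks=ranks,
        n_samples=n,
        n_rejected=n_rejected,
        seed=seed,
    )


def run_sensitivity(
    params: ParameterSet,
    free_list: Sequence[str] = DEFAULT_FREE_PARAMETERS,
    n_samples: int = 200,
    seed: Optional[int] = 0,
    grid: Optional[Sequence[tuple[float, int]]] = None,
    frequency: float = 1.0,
) -> SensitivityReport:
    """End-to-end sensitivity run on a (dt, N) evaluation lattice.

    The default lattice is a coarse 3x3 (dt in {-15, +15, -25} ms crossed
    with N in {10, 50, 100}); callers wanting the full-figure grid pass
    their own (long-running).
    """
    if grid is None:
        grid = [(dt, n) for dt in (-15.0, 15.0, -25.0) for n in (10, 50, 100)]
    samples = sample_parameter_vectors(params, free_list, n_samples, seed)
    ref_w = _grid_weights(params, grid, frequency)
    distances = []
    kept = []
    n_rejected = 0
    for vec in samples:
        try:
            d = map_distance(vec, params, grid, free_list, frequency, ref_weights=ref_w)
        except (RuntimeError, ValueError):
            n_rejected += 1
            continue
        kept.append(vec)
        distances.append(d)
    variances = 0.27 * np.array([params[name] for name in free_list]) ** 2
    return compute_src(
        np.array(kept), np.array(distances), variances, free_list, seed=seed, n_rejected=n_rejected
    )
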