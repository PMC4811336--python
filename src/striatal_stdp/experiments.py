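"""In-silico experiments: plasticity maps, knockouts, enzyme-inhibition scenarios.

A plasticity map evaluates the final synaptic weights over a grid of
(spike timing x number of pairings) or (spike timing x pairing frequency).
To emulate the 2-5 ms experimental jitter of the spike timing, W_pre and
W_post are blurred along the timing axis with a normalized Gaussian
(s.d. 3 ms) *before* W_total is recomposed as their product.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from joblib import Parallel, delayed
from scipy.ndimage import gaussian_filter1d

from .engine import run_protocol
from .parameters import ModelVariant, ParameterSet, apply_variant
from .stimuli import build_pre_only_protocol, build_stdp_protocol

__all__ = [
    "PlasticityMap",
    "compute_map",
    "compute_frequency_map",
    "gaussian_blur_dt",
    "extract_domain_boundaries",
    "scenario_suite",
]


@dataclass
class PlasticityMap:
    """Final weights over a (dt_STDP x N_pairings | frequency) grid.

    Matrices are indexed ``[i_dt, j_axis2]``.  Raw and blurred layers are
    both retained; the blur acts on W_pre and W_post separately and W_total
    is their product.
    """

    dt_grid: np.ndarray  # ms
    axis2_grid: np.ndarray  # pairing counts or frequencies
    axis2_name: str  # "n_pairings" | "frequency"
    w_pre: np.ndarray
    w_post: np.ndarray
    w_total: np.ndarray
    w_pre_blur: np.ndarray
    w_post_blur: np.ndarray
    w_total_blur: np.ndarray
    blur_sd_ms: float
    variant_label: str = "control"
    params_digest: str = ""

    def to_csv(self, path_prefix: str) -> None:
        import pandas as pd

        for name in ("w_pre", "w_post", "w_total", "w_total_blur"):
            df = pd.DataFrame(
                getattr(self, name), index=self.dt_grid, columns=self.axis2_grid
            )
            df.index.name = "dt_stdp_ms"
            df.columns.name = self.axis2_name
            df.to_csv(f"{path_prefix}_{name}.csv")


def gaussian_blur_dt(matrix: np.ndarray, dt_grid: np.ndarray, sd_ms: float) -> np.ndarray:
    """Blur along the dt axis with a normalized Gaussian (reflecting edges).

    The kernel is truncated at 4 s.d.; a constant map is preserved exactly
    and interior mass is spread sum-preservingly.
    """
    if matrix.shape[0] == 1 or sd_ms <= 0:
        return matrix.copy()
    steps = np.diff(dt_grid)
    step = steps[0]
    if not np.allclose(steps, step):
        raise ValueError("dt grid must be uniformly spaced for the Gaussian blur")
    return gaussian_filter1d(matrix, sigma=sd_ms / step, axis=0, mode="reflect", truncate=4.0)


def _run_point(params, dt, n, freq):
    proto = build_stdp_protocol(int(n), float(dt), float(freq), params)
    res = run_protocol(params, proto, record=False)
    return res.w_pre, res.w_post


def _assemble(params, variant, dt_grid, axis2_grid, axis2_name, points, n_jobs):
    dt_grid = np.asarray(dt_grid, dtype=float)
    axis2_grid = np.asarray(axis2_grid)
    results = Parallel(n_jobs=n_jobs)(
        delayed(_run_point)(params, dt, n, f) for (dt, n, f) in points
    )
    shape = (dt_grid.size, axis2_grid.size)
    w_pre = np.array([r[0] for r in results]).reshape(shape)
    w_post = np.array([r[1] for r in results]).reshape(shape)
    sd = params.blur_sd_ms
    w_pre_b = gaussian_blur_dt(w_pre, dt_grid, sd)
    w_post_b = gaussian_blur_dt(w_post, dt_grid, sd)
    return PlasticityMap(
        dt_grid=dt_grid,
        axis2_grid=axis2_grid,
        axis2_name=axis2_name,
        w_pre=w_pre,
        w_post=w_post,
        w_total=w_pre * w_post,
        w_pre_blur=w_pre_b,
        w_post_blur=w_post_b,
        w_total_blur=w_pre_b * w_post_b,
        blur_sd_ms=sd,
        variant_label=variant.label(),
        params_digest=params.digest(),
    )


def compute_map(
    params: ParameterSet,
    variant: ModelVariant,
    dt_grid: Sequence[float],
    n_grid: Sequence[int],
    frequency: float = 1.0,
    n_jobs: int = 1,
) -> PlasticityMap:
    """W_total over a (dt_STDP, N_pairings) grid at fixed pairing frequency."""
    if len(dt_grid) == 0 or len(n_grid) == 0:
        raise ValueError("grids must be non-empty")
    p = apply_variant(params, variant)
    points = [(dt, n, frequency) for dt in dt_grid for n in n_grid]
    return _assemble(p, variant, dt_grid, np.asarray(n_grid, dtype=int), "n_pairings", points, n_jobs)


def compute_frequency_map(
    params: ParameterSet,
    variant: ModelVariant,
    dt_grid: Sequence[float],
    f_grid: Sequence[float],
    n_pairings: int = 10,
    n_jobs: int = 1,
) -> PlasticityMap:
    """W_total over a (dt_STDP, frequency) grid at fixed number of pairings."""
    if len(dt_grid) == 0 or len(f_grid) == 0:
        raise ValueError("grids must be non-empty")
    p = apply_variant(params, variant)
    points = [(dt, n_pairings, f) for dt in dt_grid for f in f_grid]
    return _assemble(p, variant, dt_grid, np.asarray(f_grid, dtype=float), "frequency", points, n_jobs)


@dataclass
class Domain:
    label: str  # "LTP" | "LTD"
    dt_min: float
    dt_max: float
    axis2_min: float
    axis2_max: float
    size: int = 0

    def astuple(self):
        return (self.label, (self.dt_min, self.dt_max), (self.axis2_min, self.axis2_max))


def extract_domain_boundaries(
    pmap: PlasticityMap,
    ltp_threshold: float = 110.0,
    ltd_threshold: float = 90.0,
    blurred: bool = True,
) -> list[Domain]:
    """Connected LTP/LTD domains of the map with their axis bounds.

    Thresholds are percentages of baseline and must straddle 100%.
    """
    from scipy.ndimage import label as cc_label

    if not (ltd_threshold < 100.0 < ltp_threshold):
        raise ValueError("thresholds must straddle 100%")
    w = (pmap.w_total_blur if blurred else pmap.w_total) * 100.0
    if w.size == 0:
        raise ValueError("empty plasticity map")
    out: list[Domain] = []
    for lab, mask in (("LTP", w > ltp_threshold), ("LTD", w < ltd_threshold)):
        lbl, n_cc = cc_label(mask)
        for k in range(1, n_cc + 1):
            ii, jj = np.nonzero(lbl == k)
            out.append(
                Domain(
                    label=lab,
                    dt_min=float(pmap.dt_grid[ii.min()]),
                    dt_max=float(pmap.dt_grid[ii.max()]),
                    axis2_min=float(pmap.axis2_grid[jj.min()]),
                    axis2_max=float(pmap.axis2_grid[jj.max()]),
                    size=int(ii.size),
                )
            )
    out.sort(key=lambda d: (d.label, -d.size))
    return out


def scenario_suite(params: ParameterSet, dt_stdp_ms: float = -15.0) -> "list[dict]":
    """The three model-guided MAGL/DAGK-inhibition scenarios.

    (i) 5 post-pre pairings: control eCB-tLTP vs amplified tLTP under full
    MAGL block with DAG-kinase at 5%; (ii) 50 post-pre pairings: control
    no-plasticity gap vs tLTP uncovered by MAGL at 40%; (iii) 100
    presynaptic-only stimulations: control no change vs tLTP under full
    MAGL block with DAG-kinase at 5%.

    Inhibitors are applied acutely: every run starts from the control
    resting state (a complete MAGL block leaves 2-AG without a degradation
    path, so the fully inhibited model has no resting state of its own).
    """
    inhib_full = ModelVariant(enzyme_scales={"MAGL": 0.0, "DAGK": 0.05})
    inhib_40 = ModelVariant(enzyme_scales={"MAGL": 0.4})
    control = ModelVariant()

    def run_paired(n, variant):
        p = apply_variant(params, variant)
        proto = build_stdp_protocol(n, dt_stdp_ms, 1.0, p)
        return run_protocol(p, proto, record=False, variant_label=variant.label(),
                            init_params=params)

    def run_pre_only(n, variant):
        p = apply_variant(params, variant)
        proto = build_pre_only_protocol(n, 1.0)
        return run_protocol(p, proto, record=False, variant_label=variant.label(),
                            init_params=params)

    rows = []
    for name, runner, n, var_c, var_i in (
        ("5 post-pre pairings", run_paired, 5, control, inhib_full),
        ("50 post-pre pairings", run_paired, 50, control, inhib_40),
        ("100 pre-only stimulations", run_pre_only, 100, control, inhib_full),
    ):
        r_c = runner(n, var_c)
        r_i = runner(n, var_i)
        rows.append(
            {
                "scenario": name,
                "inhibition": var_i.label(),
                "w_total_control_pct": 100.0 * r_c.w_total,
                "w_total_inhibited_pct": 100.0 * r_i.w_total,
            }
        )
    return rows
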