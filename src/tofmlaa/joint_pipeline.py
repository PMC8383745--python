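"""The four-step joint reconstruction loop and the reference reconstruction.

Each global iteration executes, in this fixed order:

1. activity update — one OSEM iteration with attenuation factors from the
   current attenuation estimate (zero initial attenuation means no
   attenuation correction at the very first activity update);
2. attenuation update — one XMLTR iteration from the non-TOF data with the
   activity projection recomputed from the current activity estimate;
3. scaling — the scaling constant is determined from the known-attenuation
   VOI and both images are updated (lam scaled, mu shifted along the unit
   medium and clamped nonnegative);
4. additive-term refresh — a hook for scatter re-estimation; the packaged
   modes keep the supplied (or zero) scatter fixed.

A reference reconstruction (TOF OSEM with the true attenuation) is the
comparator for all evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional

import numpy as np

from .attenuation_recon import transmission_recon
from .emission_recon import loglikelihood, osem
from .metrics import percent_bias
from .phantom_sim import CorrectionSet
from .scaling import ScalingTrace, UnitMedium, VOISpec, apply_scaling, compute_unit_medium, scaling_factor
from .scanner_model import (
    ActivityImage,
    AttenuationImage,
    ImageGrid,
    ScanGeometry,
    TOFModel,
    TOFSinogram,
    get_projector,
)


class JointDivergenceError(RuntimeError):
    """Raised when |log C| grows for three consecutive global iterations."""

    def __init__(self, message: str, trace: ScalingTrace):
        super().__init__(message)
        self.trace = trace


@dataclass
class JointConfig:
    """Configuration of the four-step joint reconstruction."""

    n_global_iterations: int = 10
    activity_iterations: int = 1
    activity_subsets: int = 8
    attenuation_iterations: int = 1
    attenuation_subsets: int = 8
    initial_attenuation: object = "water"  # "zero" | "water" | ndarray
    voi: Optional[VOISpec] = None
    scatter_mode: str = "none"  # none | supplied | stub
    damping: float = 1.0
    unit_medium_iterations: int = 5
    unit_medium_subsets: int = 28
    seed: int = 0
    water_mu: float = 0.096

    def __post_init__(self) -> None:
        if self.n_global_iterations < 1:
            raise ValueError("need at least one global iteration")
        if self.scatter_mode not in ("none", "supplied", "stub"):
            raise ValueError(f"unknown scatter mode {self.scatter_mode!r}")


@dataclass
class JointResult:
    lam: ActivityImage
    mu: AttenuationImage
    trace: ScalingTrace
    diagnostics: Dict[str, list]
    unit: UnitMedium


def run_joint(y_t: TOFSinogram, corrections: Optional[CorrectionSet],
              geometry: ScanGeometry, tof: TOFModel,
              activity_grid: ImageGrid, attenuation_grid: ImageGrid,
              support_activity: np.ndarray, support_attenuation: np.ndarray,
              cfg: JointConfig, unit: Optional[UnitMedium] = None,
              object_support: Optional[np.ndarray] = None,
              truth: Optional[ActivityImage] = None,
              scatter_update: Optional[Callable] = None,
              monitor: Optional[Callable] = None) -> JointResult:
    """Run the joint reconstruction; see the module docstring for the step order.

    The unit medium may be passed in (e.g. from a cache); results are
    bit-identical for the same medium.  ``object_support`` is the object
    mask without the reconstruction margin; it defines the detectable-LOR
    set of the unit medium and the extent of the uniform-water initial
    attenuation, and defaults to ``support_attenuation``.  ``truth``
    enables per-iteration %Bias diagnostics.  ``scatter_update`` is the
    optional step-4 hook ``(lam, mu) -> TOFSinogram``; ``monitor(k, lam, mu)``
    is called after every global iteration with the current estimates.
    """
    corrections = corrections or CorrectionSet()
    yv = y_t.values
    proj_act = get_projector(geometry, activity_grid, tof)
    proj_att = get_projector(geometry, attenuation_grid)
    if object_support is None:
        object_support = support_attenuation

    if unit is None:
        unit = compute_unit_medium(proj_att, object_support,
                                   n_iter=cfg.unit_medium_iterations,
                                   n_subsets=cfg.unit_medium_subsets)
    if cfg.voi is None:
        raise ValueError("a VOI with known attenuation is required for scaling")

    norm = corrections.norm_values(yv.shape[:-1])
    if cfg.scatter_mode == "none":
        s_t = np.zeros_like(yv)
    else:
        s_t = corrections.additive_tof(yv.shape)
    y_nontof = yv.sum(axis=-1)

    lam = np.where(support_activity, 1.0, 0.0)
    if isinstance(cfg.initial_attenuation, str):
        if cfg.initial_attenuation == "zero":
            mu = np.zeros(attenuation_grid.shape)
        elif cfg.initial_attenuation == "water":
            mu = np.where(object_support, cfg.water_mu, 0.0)
        else:
            raise ValueError(f"unknown initial attenuation mode {cfg.initial_attenuation!r}")
    else:
        mu = np.asarray(cfg.initial_attenuation, dtype=np.float64).copy()

    trace = ScalingTrace()
    diagnostics: Dict[str, list] = {"loglik": [], "log_c": [], "c": []}
    if truth is not None:
        diagnostics["percent_bias"] = []
    grow_streak = 0

    for k in range(cfg.n_global_iterations):
        # (1) activity update with attenuation factors from the current mu
        a = norm * np.exp(-proj_att.forward(mu))
        state = osem(yv, a, s_t, proj_act,
                     n_iter=cfg.activity_iterations, n_subsets=cfg.activity_subsets,
                     fov_mask=support_activity, init=lam)
        lam = state.lam

        # (2) attenuation update; activity projection recomputed, never cached
        p = norm * proj_act.forward(lam)
        s_nontof = s_t.sum(axis=-1)
        tstate = transmission_recon(y_nontof, s_nontof, p, proj_att, support_attenuation,
                                    n_iter=cfg.attenuation_iterations,
                                    n_subsets=cfg.attenuation_subsets,
                                    method="xmltr", damping=cfg.damping, init=mu)
        mu = tstate.mu

        # (3) scaling determination and scaled updates of both images
        c, log_c = scaling_factor(mu, cfg.voi, unit)
        lam, mu = apply_scaling(lam, mu, c, unit)
        mu[~support_attenuation] = 0.0
        trace.append(log_c)
        diagnostics["log_c"].append(log_c)
        diagnostics["c"].append(c)

        # noise-level fluctuations of a converged trace are not divergence:
        # growth only counts while |log C| is above the convergence level
        if (len(trace.log_c) >= 2 and abs(trace.log_c[-1]) > abs(trace.log_c[-2])
                and abs(trace.log_c[-1]) > 0.01):
            grow_streak += 1
        else:
            grow_streak = 0
        if grow_streak >= 3:
            raise JointDivergenceError(
                f"|log C| grew for 3 consecutive iterations (iteration {k + 1}); "
                "joint reconstruction is diverging", trace)

        # (4) additive-term refresh (no-op unless a hook is supplied)
        if scatter_update is not None:
            refreshed = scatter_update(lam, mu)
            s_t = refreshed.values if isinstance(refreshed, TOFSinogram) else np.asarray(
                refreshed, dtype=np.float64)

        a_now = norm * np.exp(-proj_att.forward(mu))
        ybar = a_now[..., None] * proj_act.forward_tof(lam) + s_t
        diagnostics["loglik"].append(loglikelihood(yv, ybar))
        if truth is not None:
            diagnostics["percent_bias"].append(
                percent_bias(lam, truth.values, support_activity))
        if monitor is not None:
            monitor(k + 1, lam, mu)

    return JointResult(lam=ActivityImage(lam, activity_grid),
                       mu=AttenuationImage(mu, attenuation_grid),
                       trace=trace, diagnostics=diagnostics, unit=unit)


def reference_recon(y_t: TOFSinogram, mu_true: AttenuationImage,
                    corrections: Optional[CorrectionSet],
                    geometry: ScanGeometry, tof: TOFModel,
                    activity_grid: ImageGrid,
                    n_iter: int = 10, n_subsets: int = 8,
                    fov_mask: Optional[np.ndarray] = None) -> ActivityImage:
    """TOF OSEM with attenuation correction from the true attenuation image."""
    corrections = corrections or CorrectionSet()
    yv = y_t.values
    proj_act = get_projector(geometry, activity_grid, tof)
    proj_att = get_projector(geometry, mu_true.grid)
    a = corrections.norm_values(yv.shape[:-1]) * np.exp(-proj_att.forward(mu_true.values))
    s_t = corrections.additive_tof(yv.shape)
    state = osem(yv, a, s_t, proj_act, n_iter=n_iter, n_subsets=n_subsets,
                 fov_mask=fov_mask)
    return ActivityImage(state.lam, activity_grid)
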