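"""Resolution of the joint-reconstruction scale ambiguity.

TOF emission data determine activity and attenuation only up to a gauge
family ``(C lam, mu + log(C) mu_unit)``, where the unit attenuation medium
``mu_unit`` has line integral 1 on every detectable LOR through the object
support (equivalently: it multiplies every attenuation factor by e^-1).
A volume of interest (VOI) with known mean attenuation fixes the gauge:

    log C = (w^T mu_true - w^T mu_hat) / (w^T mu_unit)

and the scaled updates are ``lam <- C lam`` and
``mu <- clamp(mu + log(C) mu_unit, >= 0)``.

For a 2D disk support of radius R the unit medium has the closed form
``1 / (pi sqrt(R^2 - r^2))`` inside the disk, singular at the boundary —
which is why VOIs must avoid the support boundary.  In general the medium
is computed numerically by fitting synthetic transmission projections
(e^-1 on support-intersecting LORs, 1 elsewhere) with a few XMLTR
iterations; the residual max|chi mu_unit - 1| over interior LORs is always
reported, never silently ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .attenuation_recon import transmission_recon
from .scanner_model import AttenuationImage, ImageGrid, Projector

E_INV = float(np.exp(-1.0))


@dataclass
class UnitMedium:
    """Unit attenuation medium with its detectable-LOR set and fit residual.

    ``omega`` flags LORs whose chord through the object support exceeds the
    detectability threshold; ``interior`` additionally requires a chord
    longer than ``interior_chord_cm`` (grazing LORs are excluded there).
    """

    mu_unit: np.ndarray
    omega: np.ndarray
    interior: np.ndarray
    residual: float
    chords: np.ndarray


@dataclass(frozen=True)
class VOISpec:
    """Image-space weights plus the VOI's known mean attenuation (cm^-1)."""

    weights: np.ndarray
    mu_true: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("VOI weights must be nonnegative with positive sum")

    @staticmethod
    def disk(grid: ImageGrid, center: Tuple[float, float], diameter: float,
             mu_true: float) -> "VOISpec":
        """Uniform-weight disk VOI (a cylinder in the reduced-3D variant)."""
        xx, yy = np.meshgrid(grid.x_centers, grid.y_centers)
        m = np.hypot(xx - center[0], yy - center[1]) <= diameter / 2.0
        if grid.n_z is not None:
            m = np.broadcast_to(m, grid.shape).copy()
        return VOISpec(weights=m.astype(np.float64), mu_true=mu_true)


@dataclass
class ScalingTrace:
    """Per-global-iteration record of the scaling constant."""

    log_c: List[float] = field(default_factory=list)

    def append(self, log_c: float) -> None:
        self.log_c.append(float(log_c))

    @property
    def c(self) -> List[float]:
        return [float(np.exp(v)) for v in self.log_c]

    @property
    def final_abs_log_c(self) -> float:
        return abs(self.log_c[-1]) if self.log_c else np.nan


def detectable_lors(projector: Projector, support: np.ndarray,
                    chord_frac: float = 0.01) -> Tuple[np.ndarray, np.ndarray]:
    """LORs intersecting the object support.

    An LOR is detectable when its chord length through the support mask
    exceeds ``chord_frac`` times the support diameter (the longest chord).
    The threshold excludes grazing LORs, where attenuation recovery is
    unstable.  Returns ``(omega, chords)``.
    """
    chords = projector.forward(support.astype(np.float64))
    max_chord = chords.max()
    if max_chord <= 0:
        raise ValueError("support mask is empty")
    omega = chords > chord_frac * max_chord
    return omega, chords


def compute_unit_medium(projector: Projector, support: np.ndarray,
                        n_iter: int = 5, n_subsets: int = 28,
                        chord_frac: float = 0.01,
                        interior_chord_cm: float = 5.0) -> UnitMedium:
    """Fit the unit attenuation medium for an object support.

    Synthetic transmission projections are set to e^-1 on detectable LORs
    and 1 elsewhere; with blank-scan projection p = 1 and no additive term,
    a few XMLTR iterations restricted to the support recover an attenuation
    image whose line integrals approximate the indicator of the detectable
    set.  The worst deviation from 1 over interior LORs is reported.
    """
    omega, chords = detectable_lors(projector, support, chord_frac)
    if not omega.any():
        raise ValueError("no detectable LORs intersect the support")
    y = np.where(omega, E_INV, 1.0)
    p = np.ones_like(y)
    s = np.zeros_like(y)
    n_subsets = min(n_subsets, projector.geometry.n_angles)
    state = transmission_recon(y, s, p, projector, support,
                               n_iter=n_iter, n_subsets=n_subsets, method="xmltr")
    integrals = projector.forward(state.mu)
    interior = chords > interior_chord_cm
    residual = float(np.abs(integrals[interior] - 1.0).max()) if interior.any() else np.nan
    return UnitMedium(mu_unit=state.mu, omega=omega, interior=interior,
                      residual=residual, chords=chords)


def disk_unit_medium(grid: ImageGrid, radius: float, oversample: int = 16) -> np.ndarray:
    """Closed-form 2D disk unit medium 1/(pi sqrt(R^2 - r^2)), pixel-averaged.

    The integrable boundary singularity is handled by averaging the formula
    over an ``oversample x oversample`` sub-grid per pixel.
    """
    if oversample < 1:
        raise ValueError("oversample must be >= 1")
    offs = (np.arange(oversample) + 0.5) / oversample - 0.5
    vals = np.zeros((grid.n_y, grid.n_x))
    for oy in offs:
        for ox in offs:
            xx, yy = np.meshgrid(grid.x_centers + ox * grid.voxel_size,
                                 grid.y_centers + oy * grid.voxel_size)
            r2 = xx ** 2 + yy ** 2
            inside = r2 < radius ** 2
            f = np.zeros_like(xx)
            f[inside] = 1.0 / (np.pi * np.sqrt(radius ** 2 - r2[inside]))
            vals += f
    return vals / oversample ** 2


def scaling_factor(mu_hat, voi: VOISpec, unit: UnitMedium) -> Tuple[float, float]:
    """Scaling constant from the VOI's known mean attenuation.

    ``log C = (w^T mu_true - w^T mu_hat) / (w^T mu_unit)``; the result is
    dimensionless because the unit medium serves as the unit of measure.
    """
    mu = mu_hat.values if isinstance(mu_hat, AttenuationImage) else np.asarray(mu_hat)
    w = voi.weights
    wu = float((w * unit.mu_unit).sum())
    if wu <= 0:
        raise ValueError("VOI does not overlap the unit medium support")
    log_c = (w.sum() * voi.mu_true - float((w * mu).sum())) / wu
    return float(np.exp(log_c)), float(log_c)


def apply_scaling(lam: np.ndarray, mu: np.ndarray, c: float,
                  unit: UnitMedium) -> Tuple[np.ndarray, np.ndarray]:
    """Scaled updates: lam' = C lam, mu' = clamp(mu + log(C) mu_unit, >= 0)."""
    if c <= 0:
        raise ValueError("scaling constant must be positive")
    lam2 = c * np.asarray(lam, dtype=np.float64)
    mu2 = np.asarray(mu, dtype=np.float64) + np.log(c) * unit.mu_unit
    np.clip(mu2, 0.0, None, out=mu2)
    return lam2, mu2
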