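"""Quantitative evaluation: %Bias, contrast recovery, background variability.

%Bias is the percentage deviation of the reconstructed mean from the true
mean in a region, normalized to truth.  The contrast recovery coefficient
(CRC) for a hot lesion uses the local-shell convention: the background for
each lesion is a shell (default 4 mm thick with 4 mm clearance)
surrounding it, and

    CRC = (lesion_mean / shell_mean - 1) / (true_contrast - 1).

Background variability is the voxel-level standard deviation over the mean
inside a designated background VOI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .scanner_model import ActivityImage, ImageGrid


@dataclass(frozen=True)
class LesionSpec:
    """Hot lesion with its local background-shell definition (all in cm)."""

    center: Tuple[float, float]
    diameter: float
    true_contrast: float
    shell_thickness: float = 0.4
    shell_clearance: float = 0.4

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.true_contrast <= 1.0:
            raise ValueError("lesion needs positive diameter and contrast > 1")


def _values(img) -> np.ndarray:
    return img.values if isinstance(img, ActivityImage) else np.asarray(img, dtype=np.float64)


def percent_bias(recon, truth, region_mask: np.ndarray) -> float:
    """100 * (mean(recon) - mean(truth)) / mean(truth) over the region."""
    r, t = _values(recon), _values(truth)
    m = np.asarray(region_mask, dtype=bool)
    if not m.any():
        raise ValueError("empty evaluation region")
    t_mean = t[m].mean()
    if t_mean <= 0:
        raise ValueError("true activity must be positive on the region")
    return float(100.0 * (r[m].mean() - t_mean) / t_mean)


def disk_mask(grid: ImageGrid, center: Tuple[float, float], diameter: float) -> np.ndarray:
    xx, yy = np.meshgrid(grid.x_centers, grid.y_centers)
    m = np.hypot(xx - center[0], yy - center[1]) <= diameter / 2.0
    if grid.n_z is not None:
        m = np.broadcast_to(m, grid.shape).copy()
    return m


def lesion_and_shell_masks(grid: ImageGrid, lesion: LesionSpec,
                           support: Optional[np.ndarray] = None,
                           exclude: Optional[np.ndarray] = None
                           ) -> Tuple[np.ndarray, np.ndarray]:
    """Lesion mask and its surrounding background shell.

    The shell starts ``shell_clearance`` beyond the lesion radius and is
    ``shell_thickness`` thick; it is clipped to the support and may exclude
    other lesions via ``exclude``.
    """
    xx, yy = np.meshgrid(grid.x_centers, grid.y_centers)
    d = np.hypot(xx - lesion.center[0], yy - lesion.center[1])
    r = lesion.diameter / 2.0
    lesion_m = d <= r
    inner = r + lesion.shell_clearance
    shell_m = (d > inner) & (d <= inner + lesion.shell_thickness)
    if support is not None:
        shell_m &= support
    if exclude is not None:
        shell_m &= ~exclude
    if not lesion_m.any():
        raise ValueError(f"lesion at {lesion.center} unresolvable at this grid resolution")
    if not shell_m.any():
        raise ValueError(f"background shell empty for lesion at {lesion.center}")
    return lesion_m, shell_m


def crc_and_background_variability(recon, lesions: Sequence[LesionSpec],
                                   bg_mask: np.ndarray, grid: ImageGrid,
                                   support: Optional[np.ndarray] = None
                                   ) -> Tuple[List[float], float]:
    """Per-lesion CRC against each lesion's local shell, plus SD/mean in ``bg_mask``."""
    v = _values(recon)
    all_lesions = np.zeros(grid.shape, dtype=bool)
    for les in lesions:
        all_lesions |= disk_mask(grid, les.center, les.diameter + 2 * les.shell_clearance)
    crcs = []
    for les in lesions:
        lesion_m, shell_m = lesion_and_shell_masks(
            grid, les, support=support,
            exclude=all_lesions & ~disk_mask(grid, les.center,
                                             les.diameter + 2 * les.shell_clearance))
        shell_mean = v[shell_m].mean()
        if shell_mean <= 0:
            raise ValueError("non-positive local background mean")
        crcs.append(float((v[lesion_m].mean() / shell_mean - 1.0) / (les.true_contrast - 1.0)))
    bg = np.asarray(bg_mask, dtype=bool)
    if not bg.any():
        raise ValueError("empty background VOI")
    mean = v[bg].mean()
    variability = float(v[bg].std() / mean) if mean > 0 else np.nan
    return crcs, variability
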