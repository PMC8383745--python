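"""Parametric phantoms and Poisson TOF data simulation.

The packaged phantom is a 35 cm water cylinder (mu = 0.096 cm^-1 at
511 keV) containing a lung-like cylinder (one third of water attenuation,
8 cm diameter at (-8, 0) cm), an air cylinder (zero attenuation, 5 cm
diameter at (6, 8) cm), and three hot lesions in the activity image:
22 mm disks at contrasts 1.5 and 6 and a 37 mm disk at contrast 3.
Counts are Poisson-sampled from the forward model itself, so the simulator
expectation equals the model expectation by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .scanner_model import (
    ActivityImage,
    AttenuationImage,
    ImageGrid,
    ScanGeometry,
    Sinogram,
    TOFModel,
    TOFSinogram,
    get_projector,
)

#: linear attenuation coefficient of water at 511 keV, cm^-1
WATER_MU = 0.096
#: lung surrogate: one third of water
LUNG_MU = WATER_MU / 3.0


@dataclass(frozen=True)
class Insert:
    """A cylindrical (2D: disk) or spherical insert.

    ``activity_contrast`` multiplies the background activity inside the
    insert; ``None`` leaves activity untouched.  ``attenuation`` replaces
    the background attenuation inside; ``None`` leaves it untouched.
    ``spherical`` only matters for the reduced-3D phantom variant.
    """

    center: Tuple[float, float]
    diameter: float
    activity_contrast: Optional[float] = None
    attenuation: Optional[float] = None
    spherical: bool = False

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("insert diameter must be positive")
        if self.activity_contrast is not None and self.activity_contrast < 0:
            raise ValueError("activity contrast must be >= 0")
        if self.attenuation is not None and self.attenuation < 0:
            raise ValueError("attenuation must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Background cylinder plus inserts, with a target number of true counts."""

    background_center: Tuple[float, float] = (0.0, 0.0)
    background_diameter: float = 35.0
    background_activity: float = 1.0
    background_attenuation: float = WATER_MU
    inserts: Tuple[Insert, ...] = ()
    total_trues: float = 5e6

    def __post_init__(self) -> None:
        if self.total_trues <= 0:
            raise ValueError("total_trues must be positive")
        r_bg = self.background_diameter / 2.0
        cx, cy = self.background_center
        for ins in self.inserts:
            d = np.hypot(ins.center[0] - cx, ins.center[1] - cy)
            if d + ins.diameter / 2.0 > r_bg + 1e-9:
                raise ValueError(f"insert at {ins.center} extends outside the background cylinder")

    @property
    def lesions(self) -> Tuple[Insert, ...]:
        return tuple(i for i in self.inserts if i.activity_contrast is not None
                     and i.activity_contrast != 1.0)


def default_phantom(total_trues: float = 5e6) -> PhantomSpec:
    """The packaged evaluation phantom (see module docstring).

    Lesion locations are a fixed choice placing all three hot disks in the
    water background, clear of the lung/air cylinders.
    """
    return PhantomSpec(
        inserts=(
            Insert(center=(-8.0, 0.0), diameter=8.0, attenuation=LUNG_MU),
            Insert(center=(6.0, 8.0), diameter=5.0, attenuation=0.0),
            Insert(center=(-2.0, 7.0), diameter=2.2, activity_contrast=1.5, spherical=True),
            Insert(center=(10.0, 4.0), diameter=2.2, activity_contrast=6.0, spherical=True),
            Insert(center=(0.0, -10.0), diameter=3.7, activity_contrast=3.0, spherical=True),
        ),
        total_trues=total_trues,
    )


def _region_masks(spec: PhantomSpec, grid: ImageGrid):
    """Voxel-center membership masks for background and each insert."""
    xx, yy = np.meshgrid(grid.x_centers, grid.y_centers)
    if grid.n_z is not None:
        zc = (np.arange(grid.n_z) - (grid.n_z - 1) / 2.0) * grid.voxel_size
        zz = zc[:, None, None]
        xx = np.broadcast_to(xx, (grid.n_z,) + xx.shape)
        yy = np.broadcast_to(yy, (grid.n_z,) + yy.shape)
    else:
        zz = None
    cx, cy = spec.background_center
    bg = np.hypot(xx - cx, yy - cy) <= spec.background_diameter / 2.0
    insert_masks = []
    for ins in spec.inserts:
        r = ins.diameter / 2.0
        d2 = (xx - ins.center[0]) ** 2 + (yy - ins.center[1]) ** 2
        if zz is not None and ins.spherical:
            d2 = d2 + zz ** 2
        insert_masks.append(d2 <= r * r)
    return bg, insert_masks


def build_phantom(spec: PhantomSpec, activity_grid: ImageGrid,
                  attenuation_grid: ImageGrid) -> Tuple[ActivityImage, AttenuationImage]:
    """Rasterize the phantom; a voxel takes the value of the region owning its center.

    With 3D grids (``n_z`` set) cylinders extend through all slices and
    ``spherical`` inserts become true spheres centered on the middle slice.
    """
    for grid in (activity_grid, attenuation_grid):
        if grid.half_extent() < spec.background_diameter / 2.0:
            raise ValueError("grid too small to cover the phantom background cylinder")

    bg, ins_masks = _region_masks(spec, activity_grid)
    lam = np.where(bg, spec.background_activity, 0.0)
    for ins, m in zip(spec.inserts, ins_masks):
        if ins.activity_contrast is not None:
            lam[m] = spec.background_activity * ins.activity_contrast

    bg_a, ins_masks_a = _region_masks(spec, attenuation_grid)
    mu = np.where(bg_a, spec.background_attenuation, 0.0)
    for ins, m in zip(spec.inserts, ins_masks_a):
        if ins.attenuation is not None:
            mu[m] = ins.attenuation

    return ActivityImage(lam, activity_grid), AttenuationImage(mu, attenuation_grid)


def support_mask(spec: PhantomSpec, grid: ImageGrid, margin: float = 1.0) -> np.ndarray:
    """Object support: the background cylinder dilated by ``margin`` cm."""
    xx, yy = np.meshgrid(grid.x_centers, grid.y_centers)
    cx, cy = spec.background_center
    m = np.hypot(xx - cx, yy - cy) <= spec.background_diameter / 2.0 + margin
    if grid.n_z is not None:
        m = np.broadcast_to(m, grid.shape).copy()
    return m


@dataclass
class CorrectionSet:
    """Optional multiplicative/additive data corrections.

    ``normalization`` multiplies the true-coincidence expectation; randoms
    carry no TOF information and are spread evenly over TOF bins; scatter
    may be supplied as a TOF or non-TOF sinogram (the latter is spread
    evenly over TOF bins as well).
    """

    normalization: Optional[Sinogram] = None
    randoms: Optional[Sinogram] = None
    scatter: Optional[object] = None  # Sinogram or TOFSinogram

    def norm_values(self, shape) -> np.ndarray:
        if self.normalization is None:
            return np.ones(shape)
        v = self.normalization.values
        if np.any(v <= 0):
            raise ValueError("normalization factors must be positive")
        return v

    def additive_tof(self, shape_tof) -> np.ndarray:
        """Total additive expectation s_t = scatter_t + randoms/n_tof."""
        n_tof = shape_tof[-1]
        s = np.zeros(shape_tof)
        if self.scatter is not None:
            if isinstance(self.scatter, TOFSinogram):
                s += self.scatter.values
            else:
                v = self.scatter.values if isinstance(self.scatter, Sinogram) else np.asarray(self.scatter)
                s += v[..., None] / n_tof
        if self.randoms is not None:
            s += self.randoms.values[..., None] / n_tof
        return s


@dataclass
class SimulationResult:
    counts: TOFSinogram
    expectation: TOFSinogram
    trues_scale: float

    @property
    def scaled_truth_factor(self) -> float:
        """Multiply the input activity by this to get the simulated-scale truth."""
        return self.trues_scale


def simulate_tof_counts(lam: ActivityImage, mu: AttenuationImage,
                        corrections: Optional[CorrectionSet],
                        total_trues: float, seed: int,
                        geometry: ScanGeometry, tof: TOFModel) -> SimulationResult:
    """Poisson TOF counts from the forward model.

    The expected trues ``n * exp(-chi mu) * H_t lambda`` are rescaled so
    their total equals ``total_trues``; additive scatter/randoms are added
    on top of the rescaled trues.  Returns the counts together with the
    exact expectation used and the applied activity scale.
    """
    if total_trues <= 0:
        raise ValueError("total_trues must be positive")
    corrections = corrections or CorrectionSet()
    proj_act = get_projector(geometry, lam.grid, tof)
    proj_att = get_projector(geometry, mu.grid)
    if np.any(mu.values < 0) or np.any(lam.values < 0):
        raise ValueError("activity and attenuation must be nonnegative")

    ht = proj_act.forward_tof(lam.values)
    atten = np.exp(-proj_att.forward(mu.values))
    norm = corrections.norm_values(atten.shape)
    trues = norm[..., None] * atten[..., None] * ht
    total = trues.sum()
    if total <= 0:
        scale = 1.0
    else:
        scale = total_trues / total
    ybar = scale * trues + corrections.additive_tof(trues.shape)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(ybar).astype(np.float64)
    return SimulationResult(
        counts=TOFSinogram(counts, kind="counts"),
        expectation=TOFSinogram(ybar, kind="expectation"),
        trues_scale=scale,
    )


def stub_scatter(expected_trues: TOFSinogram, fraction: float = 0.2,
                 radial_sigma_cm: float = 4.0, geometry: Optional[ScanGeometry] = None) -> TOFSinogram:
    """A known smooth additive sinogram exercising the scatter-dependent terms.

    Built by heavily smoothing the non-TOF trues expectation along the
    radial axis and spreading it evenly over TOF bins; scaled so its total
    is ``fraction`` of the total trues.  This is a synthetic stand-in shaped
    like a broad scatter background, not a physical scatter estimate.
    """
    v = expected_trues.values
    nontof = v.sum(axis=-1)
    if geometry is not None:
        dr = 2 * geometry.fov_radius / (geometry.n_radial - 1)
    else:
        dr = 1.0
    smooth = gaussian_filter(nontof, sigma=(radial_sigma_cm / dr, 0))
    total = smooth.sum()
    if total > 0:
        smooth *= fraction * nontof.sum() / total
    n_tof = v.shape[-1]
    return TOFSinogram(np.repeat(smooth[..., None], n_tof, axis=-1) / n_tof, kind="expectation")


def normalization_from_cylinder(geometry: ScanGeometry, grid: ImageGrid,
                                diameter: float = 40.0) -> Sinogram:
    """Emulate normalization-factor generation from a uniform cylinder.

    Projects a uniform cylinder and divides the analytic chord lengths by
    the projected values; LORs missing the cylinder get factor 1.  With the
    model-based projector the factors are close to one and mainly capture
    discretization effects.
    """
    proj = get_projector(geometry, grid)
    xx, yy = np.meshgrid(grid.x_centers, grid.y_centers)
    cyl = (np.hypot(xx, yy) <= diameter / 2.0).astype(np.float64)
    projected = proj.forward(cyl)
    r = geometry.radial_positions
    rr = np.abs(r)[:, None]
    half = diameter / 2.0
    analytic = np.where(rr < half, 2.0 * np.sqrt(np.maximum(half ** 2 - rr ** 2, 0.0)), 0.0)
    analytic = np.broadcast_to(analytic, projected.shape)
    factors = np.ones_like(projected)
    ok = projected > 1e-6
    factors[ok] = analytic[ok] / projected[ok]
    factors[factors <= 0] = 1.0
    return Sinogram(factors, kind="correction-factor")
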