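"""Scanner geometry, TOF model and matched projection operators.

The scanner is described in parallel-beam style: every line of response
(LOR) is parameterized by a radial offset ``r`` and an angle ``phi`` in
``[0, pi)``.  Emission data additionally carry a time-of-flight (TOF) index
that localizes the annihilation point along the LOR with a Gaussian kernel
derived from the coincidence timing resolution.

Both the emission operator ``H`` (and its per-TOF-bin components ``H_t``)
and the transmission operator ``chi`` are built from one Siddon ray
engine computing exact chord lengths through square pixels.  The discrete
operators are stored explicitly as sparse triplets, so the backprojector
is the exact transpose of the forward projector and adjointness holds to
floating-point round-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import ndtr

#: speed of light in cm per picosecond
C_LIGHT_CM_PER_PS = 0.0299792458

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


@dataclass(frozen=True)
class ScanGeometry:
    """Ring-scanner description with parallel-beam LOR binning.

    Parameters
    ----------
    ring_diameter : float
        Detector ring diameter in cm.
    n_radial : int
        Number of radial bins; radial samples span ``[-fov_radius, fov_radius]``.
    n_angles : int
        Number of projection angles over ``[0, pi)``.
    fov_radius : float
        Transaxial field-of-view radius in cm.
    n_rings, ring_spacing, max_ring_difference
        Optional axial description for the reduced-3D (stacked direct-plane
        slices) variant; ``max_ring_difference`` is fixed at 0.
    """

    ring_diameter: float = 84.2
    n_radial: int = 193
    n_angles: int = 96
    fov_radius: float = 19.2
    n_rings: int = 1
    ring_spacing: float = 0.4
    max_ring_difference: int = 0

    def __post_init__(self) -> None:
        if self.fov_radius >= self.ring_diameter / 2.0:
            raise ValueError("fov_radius must be smaller than the ring radius")
        if self.n_radial < 1 or self.n_angles < 1:
            raise ValueError("n_radial and n_angles must be >= 1")
        if self.n_rings < 1:
            raise ValueError("n_rings must be >= 1")
        if self.max_ring_difference != 0:
            raise ValueError("only direct planes (max_ring_difference=0) are supported")

    @property
    def radial_positions(self) -> np.ndarray:
        """Radial sample positions in cm, symmetric about 0."""
        return np.linspace(-self.fov_radius, self.fov_radius, self.n_radial)

    @property
    def angles(self) -> np.ndarray:
        """Projection angles in radians over [0, pi)."""
        return np.arange(self.n_angles) * np.pi / self.n_angles

    @property
    def n_lors(self) -> int:
        return self.n_radial * self.n_angles


@dataclass(frozen=True)
class TOFModel:
    """Gaussian TOF kernel along the LOR.

    The spatial kernel FWHM is ``c * timing_fwhm / 2`` because a timing
    difference ``dt`` displaces the localized annihilation point by
    ``c*dt/2`` along the LOR.  Kernel weights per TOF bin are bin-integrated
    Gaussians, truncated at ``kernel_truncation`` sigma and renormalized so
    that the weights for any fixed emission point sum to one (hence the
    TOF components H_t marginalize exactly to the non-TOF operator H).
    """

    timing_resolution_fwhm_ps: float = 300.0
    n_tof_bins: int = 13
    tof_bin_width: float = 3.0
    kernel_truncation: float = 3.0

    def __post_init__(self) -> None:
        if self.n_tof_bins < 1 or self.n_tof_bins % 2 == 0:
            raise ValueError("n_tof_bins must be a positive odd integer")
        if self.timing_resolution_fwhm_ps <= 0 or self.tof_bin_width <= 0:
            raise ValueError("timing resolution and bin width must be positive")

    @property
    def spatial_fwhm_cm(self) -> float:
        return C_LIGHT_CM_PER_PS * self.timing_resolution_fwhm_ps / 2.0

    @property
    def sigma_cm(self) -> float:
        return self.spatial_fwhm_cm / _FWHM_TO_SIGMA

    @property
    def bin_edges(self) -> np.ndarray:
        """TOF bin edges in cm along the LOR, centered on the scanner axis."""
        half = self.n_tof_bins * self.tof_bin_width / 2.0
        return np.linspace(-half, half, self.n_tof_bins + 1)

    @property
    def bin_centers(self) -> np.ndarray:
        e = self.bin_edges
        return 0.5 * (e[:-1] + e[1:])

    def covers(self, geometry: ScanGeometry) -> bool:
        return self.n_tof_bins * self.tof_bin_width >= 2.0 * geometry.fov_radius

    def bin_weights(self, ell: np.ndarray) -> np.ndarray:
        """Normalized TOF bin weights for emission points at positions ``ell``.

        Returns an array of shape ``ell.shape + (n_tof_bins,)`` whose last
        axis sums to 1 wherever any bin survives truncation; the bin nearest
        to the emission point is always kept so the sum is exactly 1.
        """
        ell = np.asarray(ell, dtype=np.float64)
        edges = self.bin_edges.copy()
        # open-ended outer bins: overflow mass is attributed to the edge bins
        lo = np.full(self.n_tof_bins, -np.inf)
        hi = np.full(self.n_tof_bins, np.inf)
        lo[1:] = edges[1:-1]
        hi[:-1] = edges[1:-1]
        z = ell[..., None]
        w = ndtr((hi - z) / self.sigma_cm) - ndtr((lo - z) / self.sigma_cm)
        dist = np.abs(self.bin_centers - z)
        keep = dist <= self.kernel_truncation * self.sigma_cm
        nearest = np.argmin(dist, axis=-1)
        np.put_along_axis(keep, nearest[..., None], True, axis=-1)
        w = np.where(keep, w, 0.0)
        w /= w.sum(axis=-1, keepdims=True)
        return w


@dataclass(frozen=True)
class ImageGrid:
    """Regular image grid; a voxel's center defines its coordinate.

    ``origin`` is the offset (cm) of the grid center from the scanner axis.
    Activity and attenuation may live on different grids (by default the
    activity grid is 2x finer); :func:`downsample2` / :func:`upsample2`
    form the adjoint-consistent resampling pair between them.
    """

    n_x: int
    n_y: int
    voxel_size: float
    origin: tuple = (0.0, 0.0)
    n_z: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_x < 1 or self.n_y < 1 or self.voxel_size <= 0:
            raise ValueError("grid dimensions must be positive")

    @property
    def x_centers(self) -> np.ndarray:
        return (np.arange(self.n_x) - (self.n_x - 1) / 2.0) * self.voxel_size + self.origin[0]

    @property
    def y_centers(self) -> np.ndarray:
        return (np.arange(self.n_y) - (self.n_y - 1) / 2.0) * self.voxel_size + self.origin[1]

    @property
    def shape(self) -> tuple:
        if self.n_z is None:
            return (self.n_y, self.n_x)
        return (self.n_z, self.n_y, self.n_x)

    def half_extent(self) -> float:
        return max(
            abs(self.origin[0]) + self.n_x * self.voxel_size / 2.0,
            abs(self.origin[1]) + self.n_y * self.voxel_size / 2.0,
        )

    def fits_fov(self, geometry: ScanGeometry, tol: float = 1e-9) -> bool:
        return self.half_extent() <= geometry.fov_radius + tol

    def radius_map(self) -> np.ndarray:
        xx, yy = np.meshgrid(self.x_centers, self.y_centers)
        return np.hypot(xx, yy)


@dataclass
class Sinogram:
    """Non-TOF projection data indexed by (radial, angle[, slice])."""

    values: np.ndarray
    kind: str = "counts"  # counts | expectation | correction-factor

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)


@dataclass
class TOFSinogram:
    """TOF projection data; the TOF bin is the last axis."""

    values: np.ndarray
    kind: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    def to_nontof(self) -> Sinogram:
        """Marginalize over TOF bins: y = sum_t y_t."""
        return Sinogram(self.values.sum(axis=-1), kind=self.kind)


@dataclass
class ActivityImage:
    """Nonnegative activity concentration on a regular grid."""

    values: np.ndarray
    grid: ImageGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(f"image shape {self.values.shape} != grid shape {self.grid.shape}")


@dataclass
class AttenuationImage:
    """Nonnegative linear attenuation coefficients (cm^-1) on a regular grid."""

    values: np.ndarray
    grid: ImageGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(f"image shape {self.values.shape} != grid shape {self.grid.shape}")


class Projector:
    """Siddon exact-chord line-integral operator for one (geometry, grid) pair.

    Each matrix element is the exact chord length of the LOR through a
    square pixel, so the projection of a single-pixel image is exactly
    ``value x chord length``.  The system matrix is precomputed as flat
    triplet arrays grouped by angle, so ordered-subsets updates can
    restrict forward/back projection to an angle subset without touching
    the rest of the matrix; the backprojector is the exact transpose.
    When a :class:`TOFModel` is attached, per-nonzero TOF bin weights are
    precomputed from the chord midpoint position along the LOR.
    """

    def __init__(self, geometry: ScanGeometry, grid: ImageGrid, tof: Optional[TOFModel] = None):
        if not grid.fits_fov(geometry):
            raise ValueError("image grid extends beyond the scanner field of view")
        if tof is not None and not tof.covers(geometry):
            raise ValueError("TOF bins do not cover the field of view diameter")
        self.geometry = geometry
        self.grid = grid
        self.tof = tof
        self._build()

    def _build(self) -> None:
        g, grid = self.geometry, self.grid
        r = g.radial_positions
        dx = grid.voxel_size
        x_lo = grid.x_centers[0] - dx / 2.0
        y_lo = grid.y_centers[0] - dx / 2.0
        x_edges = x_lo + dx * np.arange(grid.n_x + 1)
        y_edges = y_lo + dx * np.arange(grid.n_y + 1)

        rows_l, cols_l, vals_l, ells_l = [], [], [], []
        ptr = [0]
        total = 0
        big = 1e30
        for ai, phi in enumerate(g.angles):
            s, c = np.sin(phi), np.cos(phi)
            # ray: (x, y)(ell) = (r cos - ell sin, r sin + ell cos)
            with np.errstate(divide="ignore", invalid="ignore"):
                if abs(s) > 1e-12:
                    lx = (r[:, None] * c - x_edges[None, :]) / s     # (n_radial, n_x+1)
                else:
                    lx = np.full((g.n_radial, x_edges.size), big)
                if abs(c) > 1e-12:
                    ly = (y_edges[None, :] - r[:, None] * s) / c     # (n_radial, n_y+1)
                else:
                    ly = np.full((g.n_radial, y_edges.size), big)
            # entry/exit of the grid bounding box along the ray
            lmin = np.full(g.n_radial, -big)
            lmax = np.full(g.n_radial, big)
            if abs(s) > 1e-12:
                lo, hi = np.minimum(lx[:, 0], lx[:, -1]), np.maximum(lx[:, 0], lx[:, -1])
                lmin, lmax = np.maximum(lmin, lo), np.minimum(lmax, hi)
            else:
                inside = (r * c >= x_edges[0]) & (r * c <= x_edges[-1])
                lmax = np.where(inside, lmax, -big)
            if abs(c) > 1e-12:
                lo, hi = np.minimum(ly[:, 0], ly[:, -1]), np.maximum(ly[:, 0], ly[:, -1])
                lmin, lmax = np.maximum(lmin, lo), np.minimum(lmax, hi)
            else:
                inside = (r * s >= y_edges[0]) & (r * s <= y_edges[-1])
                lmax = np.where(inside, lmax, -big)

            crossings = np.concatenate([lx, ly], axis=1)
            crossings = np.clip(crossings, lmin[:, None], lmax[:, None])
            crossings.sort(axis=1)
            seg_len = np.diff(crossings, axis=1)
            mid = 0.5 * (crossings[:, :-1] + crossings[:, 1:])
            x_mid = r[:, None] * c - mid * s
            y_mid = r[:, None] * s + mid * c
            ix = np.floor((x_mid - x_lo) / dx).astype(np.int64)
            iy = np.floor((y_mid - y_lo) / dx).astype(np.int64)
            ok = (seg_len > 1e-12) & (ix >= 0) & (ix < grid.n_x) & (iy >= 0) & (iy < grid.n_y)
            if ok.any():
                lor = np.broadcast_to(np.arange(g.n_radial)[:, None], ok.shape)
                rows_l.append((ai * g.n_radial + lor[ok]).astype(np.int64))
                cols_l.append(iy[ok] * grid.n_x + ix[ok])
                vals_l.append(seg_len[ok])
                ells_l.append(mid[ok])
                total += int(ok.sum())
            ptr.append(total)

        self.rows = np.concatenate(rows_l) if rows_l else np.empty(0, np.int64)
        self.cols = np.concatenate(cols_l) if cols_l else np.empty(0, np.int64)
        self.vals = np.concatenate(vals_l) if vals_l else np.empty(0, np.float64)
        self.ells = np.concatenate(ells_l) if ells_l else np.empty(0, np.float64)
        self.angle_ptr = np.asarray(ptr, dtype=np.int64)
        self.n_lors = g.n_lors
        self.n_pix = grid.n_x * grid.n_y
        if self.tof is not None:
            self.tof_weights = self.tof.bin_weights(self.ells)
        else:
            self.tof_weights = None

    # -- subset bookkeeping ------------------------------------------------
    def _select(self, angle_subset):
        if angle_subset is None:
            return slice(None)
        parts = [np.arange(self.angle_ptr[a], self.angle_ptr[a + 1]) for a in angle_subset]
        return np.concatenate(parts) if parts else np.empty(0, np.int64)

    # -- non-TOF -----------------------------------------------------------
    def forward(self, image: np.ndarray, angle_subset=None) -> np.ndarray:
        """Line integrals of ``image``; returns (n_radial, n_angles).

        With ``angle_subset`` only the selected angle columns are computed,
        the rest are zero.
        """
        img = np.asarray(image, dtype=np.float64).ravel()
        if img.size != self.n_pix:
            raise ValueError("image shape does not match the projector grid")
        sel = self._select(angle_subset)
        contrib = self.vals[sel] * img[self.cols[sel]]
        out = np.bincount(self.rows[sel], weights=contrib, minlength=self.n_lors)
        return out.reshape(self.geometry.n_angles, self.geometry.n_radial).T

    def back(self, sino: np.ndarray, angle_subset=None) -> np.ndarray:
        """Adjoint of :meth:`forward` (exact transpose)."""
        s = np.asarray(sino, dtype=np.float64)
        if s.shape != (self.geometry.n_radial, self.geometry.n_angles):
            raise ValueError("sinogram shape does not match the projector geometry")
        flat = s.T.ravel()
        sel = self._select(angle_subset)
        contrib = self.vals[sel] * flat[self.rows[sel]]
        out = np.bincount(self.cols[sel], weights=contrib, minlength=self.n_pix)
        return out.reshape(self.grid.n_y, self.grid.n_x)

    # -- TOF ---------------------------------------------------------------
    def forward_tof(self, image: np.ndarray, angle_subset=None) -> np.ndarray:
        """Per-TOF-bin line integrals H_t(image); returns (n_radial, n_angles, n_tof)."""
        if self.tof_weights is None:
            raise ValueError("projector was built without a TOF model")
        img = np.asarray(image, dtype=np.float64).ravel()
        if img.size != self.n_pix:
            raise ValueError("image shape does not match the projector grid")
        sel = self._select(angle_subset)
        z = self.vals[sel] * img[self.cols[sel]]
        rows = self.rows[sel]
        w = self.tof_weights[sel]
        nt = self.tof.n_tof_bins
        out = np.empty((self.n_lors, nt))
        for t in range(nt):
            out[:, t] = np.bincount(rows, weights=z * w[:, t], minlength=self.n_lors)
        return out.reshape(self.geometry.n_angles, self.geometry.n_radial, nt).transpose(1, 0, 2)

    def back_tof(self, sino_t: np.ndarray, angle_subset=None) -> np.ndarray:
        """Adjoint of :meth:`forward_tof`: sum_t H_t^T y_t."""
        if self.tof_weights is None:
            raise ValueError("projector was built without a TOF model")
        nt = self.tof.n_tof_bins
        s = np.asarray(sino_t, dtype=np.float64)
        if s.shape != (self.geometry.n_radial, self.geometry.n_angles, nt):
            raise ValueError("TOF sinogram shape does not match the projector")
        flat = s.transpose(1, 0, 2).reshape(self.n_lors, nt)
        sel = self._select(angle_subset)
        rows = self.rows[sel]
        w = self.tof_weights[sel]
        g = np.zeros(rows.size)
        for t in range(nt):
            g += w[:, t] * flat[rows, t]
        contrib = self.vals[sel] * g
        out = np.bincount(self.cols[sel], weights=contrib, minlength=self.n_pix)
        return out.reshape(self.grid.n_y, self.grid.n_x)


# ---------------------------------------------------------------------------
# projector cache and typed operation wrappers

_PROJECTOR_CACHE: dict = {}


def get_projector(geometry: ScanGeometry, grid: ImageGrid, tof: Optional[TOFModel] = None) -> Projector:
    """Build (or reuse a cached) projector for this geometry/grid/TOF triple."""
    key = (geometry, grid, tof)
    if key not in _PROJECTOR_CACHE:
        _PROJECTOR_CACHE[key] = Projector(geometry, grid, tof)
    return _PROJECTOR_CACHE[key]


def clear_projector_cache() -> None:
    _PROJECTOR_CACHE.clear()


def _per_slice(fn, values, out_builder):
    if values.ndim == 2:
        return fn(values)
    return np.stack([fn(values[z]) for z in range(values.shape[0])], axis=out_builder)


def forward_emission_tof(lam: ActivityImage, geometry: ScanGeometry, tof: TOFModel) -> TOFSinogram:
    """Compute H_t(lambda) per TOF bin (attenuation/scatter applied by caller)."""
    if np.any(lam.values < 0):
        raise ValueError("activity must be nonnegative")
    proj = get_projector(geometry, lam.grid, tof)
    if lam.values.ndim == 2:
        out = proj.forward_tof(lam.values)
    else:
        out = np.stack([proj.forward_tof(lam.values[z]) for z in range(lam.values.shape[0])], axis=2)
    return TOFSinogram(out, kind="expectation")


def forward_emission_nontof(lam: ActivityImage, geometry: ScanGeometry) -> Sinogram:
    if np.any(lam.values < 0):
        raise ValueError("activity must be nonnegative")
    proj = get_projector(geometry, lam.grid)
    if lam.values.ndim == 2:
        out = proj.forward(lam.values)
    else:
        out = np.stack([proj.forward(lam.values[z]) for z in range(lam.values.shape[0])], axis=2)
    return Sinogram(out, kind="expectation")


def backproject_emission(y, geometry: ScanGeometry, grid: ImageGrid, tof: Optional[TOFModel] = None) -> np.ndarray:
    """Adjoint emission operator: H^T y for a Sinogram, sum_t H_t^T y_t for TOF data."""
    if isinstance(y, TOFSinogram):
        proj = get_projector(geometry, grid, tof)
        return proj.back_tof(y.values)
    vals = y.values if isinstance(y, Sinogram) else np.asarray(y)
    proj = get_projector(geometry, grid)
    if vals.ndim == 2:
        return proj.back(vals)
    return np.stack([proj.back(vals[:, :, z]) for z in range(vals.shape[2])], axis=0)


def forward_attenuation(mu: AttenuationImage, geometry: ScanGeometry) -> Sinogram:
    """Line integrals chi*mu (dimensionless); attenuation factors are exp(-chi*mu)."""
    if np.any(mu.values < 0):
        raise ValueError("attenuation must be nonnegative")
    proj = get_projector(geometry, mu.grid)
    if mu.values.ndim == 2:
        out = proj.forward(mu.values)
    else:
        out = np.stack([proj.forward(mu.values[z]) for z in range(mu.values.shape[0])], axis=2)
    return Sinogram(out, kind="expectation")


def backproject_attenuation(q: Sinogram, geometry: ScanGeometry, grid: ImageGrid) -> np.ndarray:
    vals = q.values if isinstance(q, Sinogram) else np.asarray(q)
    proj = get_projector(geometry, grid)
    if vals.ndim == 2:
        return proj.back(vals)
    return np.stack([proj.back(vals[:, :, z]) for z in range(vals.shape[2])], axis=0)


# ---------------------------------------------------------------------------
# fine/coarse grid resampling (activity grid is 2x finer than attenuation)

def downsample2(image: np.ndarray) -> np.ndarray:
    """2x2 block mean, mapping a fine grid to a 2x coarser one."""
    a = np.asarray(image, dtype=np.float64)
    ny, nx = a.shape[-2:]
    if ny % 2 or nx % 2:
        raise ValueError("image dimensions must be even for 2x downsampling")
    return a.reshape(*a.shape[:-2], ny // 2, 2, nx // 2, 2).mean(axis=(-3, -1))


def upsample2(image: np.ndarray, adjoint: bool = False) -> np.ndarray:
    """Nearest-neighbour 2x upsampling.

    With ``adjoint=True`` the result is divided by 4 so that
    ``<downsample2(x), y> == <x, upsample2(y, adjoint=True)>`` exactly.
    """
    a = np.asarray(image, dtype=np.float64)
    out = np.repeat(np.repeat(a, 2, axis=-2), 2, axis=-1)
    return out / 4.0 if adjoint else out


def coarse_grid(grid: ImageGrid) -> ImageGrid:
    """The 2x coarser grid aligned with ``grid`` (same physical extent)."""
    if grid.n_x % 2 or grid.n_y % 2:
        raise ValueError("grid dimensions must be even")
    return ImageGrid(grid.n_x // 2, grid.n_y // 2, grid.voxel_size * 2.0,
                     origin=grid.origin, n_z=grid.n_z)
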