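"""Projector and geometry contracts: oracle agreement, adjointness,
TOF marginalization, symmetries, and input validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tofmlaa import (
    ActivityImage,
    AttenuationImage,
    ImageGrid,
    ScanGeometry,
    Sinogram,
    TOFModel,
    TOFSinogram,
    coarse_grid,
    downsample2,
    forward_attenuation,
    forward_emission_nontof,
    forward_emission_tof,
    upsample2,
)
from tofmlaa.scanner_model import Projector, get_projector


def march_chord(grid, iy, ix, r, phi, step=1e-4, tof=None, tof_bin=None, half_length=8.0):
    """Fine-step ray-marching oracle: length of the LOR (r, phi) inside the
    square pixel (iy, ix), optionally weighted by the TOF bin kernel."""
    ell = np.arange(-half_length, half_length, step) + step / 2
    x = r * np.cos(phi) - ell * np.sin(phi)
    y = r * np.sin(phi) + ell * np.cos(phi)
    half = grid.voxel_size / 2.0
    inside = ((np.abs(x - grid.x_centers[ix]) <= half)
              & (np.abs(y - grid.y_centers[iy]) <= half))
    if tof is None:
        return inside.sum() * step
    w = tof.bin_weights(ell)[:, tof_bin]
    return float((inside * w).sum() * step)


def _clear_of_pixel_edges(grid, r, phi, iy, ix, eps=1e-6):
    # exactly edge-tangent rays are a measure-zero tie-break ambiguity
    d = abs(r - (grid.x_centers[ix] * np.cos(phi) + grid.y_centers[iy] * np.sin(phi)))
    half = grid.voxel_size / 2.0
    return abs(d - half) > 1e-3 and abs(d - half * np.sqrt(2)) > 1e-3


class TestSinglePixelOracle:
    def test_nontof_matches_fine_step_ray_marching(self, small_geom, small_grid):
        proj = get_projector(small_geom, small_grid)
        img = np.zeros(small_grid.shape)
        iy, ix = 16, 18
        img[iy, ix] = 1.0
        sino = proj.forward(img)
        checked = 0
        for ai, phi in enumerate(small_geom.angles):
            for ri, r in enumerate(small_geom.radial_positions):
                v = sino[ri, ai]
                if v > 0.05 and _clear_of_pixel_edges(small_grid, r, phi, iy, ix):
                    oracle = march_chord(small_grid, iy, ix, r, phi)
                    assert v == pytest.approx(oracle, rel=1e-3)
                    checked += 1
        assert checked > 20

    def test_tof_matches_fine_step_ray_marching(self, small_geom, small_grid, small_tof):
        proj = get_projector(small_geom, small_grid, small_tof)
        img = np.zeros(small_grid.shape)
        iy, ix = 14, 17
        img[iy, ix] = 1.0
        sino = proj.forward_tof(img)
        checked = 0
        for ai in range(0, small_geom.n_angles, 5):
            phi = small_geom.angles[ai]
            for ri, r in enumerate(small_geom.radial_positions):
                if not _clear_of_pixel_edges(small_grid, r, phi, iy, ix):
                    continue
                for t in range(small_tof.n_tof_bins):
                    v = sino[ri, ai, t]
                    if v > 0.02:
                        oracle = march_chord(small_grid, iy, ix, r, phi,
                                             step=1e-3, tof=small_tof, tof_bin=t)
                        assert v == pytest.approx(oracle, rel=1e-2)
                        checked += 1
        assert checked > 10


class TestAdjointness:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_nontof_adjoint_identity(self, small_proj_nontof, seed):
        rng = np.random.default_rng(seed)
        x = rng.random(small_proj_nontof.grid.shape)
        y = rng.random((small_proj_nontof.geometry.n_radial,
                        small_proj_nontof.geometry.n_angles))
        lhs = float((small_proj_nontof.forward(x) * y).sum())
        rhs = float((x * small_proj_nontof.back(y)).sum())
        assert lhs == pytest.approx(rhs, rel=1e-10)

    @pytest.mark.parametrize("seed", [0, 3])
    def test_tof_adjoint_identity(self, small_proj, small_tof, seed):
        rng = np.random.default_rng(seed)
        x = rng.random(small_proj.grid.shape)
        y = rng.random((small_proj.geometry.n_radial, small_proj.geometry.n_angles,
                        small_tof.n_tof_bins))
        lhs = float((small_proj.forward_tof(x) * y).sum())
        rhs = float((x * small_proj.back_tof(y)).sum())
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_resampling_pair_adjoint(self):
        rng = np.random.default_rng(5)
        fine = rng.random((16, 16))
        coarse = rng.random((8, 8))
        lhs = float((downsample2(fine) * coarse).sum())
        rhs = float((fine * upsample2(coarse, adjoint=True)).sum())
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestTOFStructure:
    def test_marginalization_equals_nontof(self, small_proj):
        rng = np.random.default_rng(7)
        x = rng.random(small_proj.grid.shape)
        full = small_proj.forward(x)
        marg = small_proj.forward_tof(x).sum(axis=-1)
        assert np.abs(marg - full).max() <= 1e-8 * max(full.max(), 1.0)

    def test_point_source_tof_profile_symmetric(self, small_geom, small_grid, small_tof):
        proj = get_projector(small_geom, small_grid, small_tof)
        img = np.zeros(small_grid.shape)
        # four central pixels form a centrally-symmetric source at the axis
        img[15:17, 15:17] = 1.0
        sino = proj.forward_tof(img)
        # LORs through the scanner center (r = 0) see a source symmetric
        # about ell = 0, so their TOF profile is even in the bin index
        central = small_geom.n_radial // 2
        prof = sino[central, :, :]
        assert np.allclose(prof, prof[:, ::-1], atol=1e-12 * sino.max())

    @given(st.floats(-9.0, 9.0), st.floats(-9.0, 9.0))
    @settings(max_examples=30, deadline=None)
    def test_bin_weights_sum_to_one(self, a, b):
        tof = TOFModel(n_tof_bins=7, tof_bin_width=2.0)
        w = tof.bin_weights(np.array([a, b]))
        assert np.allclose(w.sum(axis=-1), 1.0, atol=1e-12)
        assert np.all(w >= 0)

    def test_spatial_kernel_from_timing(self):
        tof = TOFModel(timing_resolution_fwhm_ps=300.0)
        # c * 300 ps / 2 = 4.497 cm
        assert tof.spatial_fwhm_cm == pytest.approx(4.4969, abs=1e-3)


class TestSymmetryAndTrivia:
    def test_zero_image_projects_to_zero(self, small_proj):
        z = np.zeros(small_proj.grid.shape)
        assert not small_proj.forward(z).any()
        assert not small_proj.forward_tof(z).any()

    def test_backproject_zero_is_zero(self, small_proj_nontof, small_geom):
        z = np.zeros((small_geom.n_radial, small_geom.n_angles))
        assert not small_proj_nontof.back(z).any()

    def test_sensitivity_positive_inside_fov(self, small_proj_nontof, small_geom):
        ones = np.ones((small_geom.n_radial, small_geom.n_angles))
        sens = small_proj_nontof.back(ones)
        rr = small_proj_nontof.grid.radius_map()
        assert np.all(sens[rr < 0.9 * small_geom.fov_radius] > 0)

    def test_centered_disk_sinogram_angle_invariant_and_even(self, small_proj_nontof,
                                                            small_geom, small_grid):
        rr = small_grid.radius_map()
        disk = (rr <= 4.0).astype(float)
        sino = small_proj_nontof.forward(disk)
        # away from the tangent bins (where the pixelized rim dominates)
        interior = np.abs(small_geom.radial_positions) <= 0.8 * 4.0 + 1e-9
        # axis-aligned angles have every ray on a pixel edge; their floor
        # tie-break shifts the column by one bin, so skip them here
        angles = small_geom.angles
        generic = np.minimum(np.abs(np.sin(angles)), np.abs(np.cos(angles))) > 1e-9
        cols = sino[np.ix_(interior, generic)]
        tol = 3.0 * small_grid.voxel_size
        ref = cols[:, 0]
        for j in range(cols.shape[1]):
            assert np.abs(cols[:, j] - ref).max() < tol
        # the pixelized disk is centrally symmetric, so r -> -r is exact
        # for every non-tie angle
        assert np.abs(cols - cols[::-1, :]).max() < 1e-9

    def test_water_disk_chord_integral(self, small_geom, small_grid):
        # central LOR through a water disk: integral = mu * diameter
        mu_w = 0.096
        rr = small_grid.radius_map()
        mu = AttenuationImage(np.where(rr <= 5.0, mu_w, 0.0), small_grid)
        sino = forward_attenuation(mu, small_geom)
        center = small_geom.n_radial // 2
        # continuous chord 0.096 * 10 cm, up to voxel-center rasterization
        assert sino.values[center, 0] == pytest.approx(
            mu_w * 10.0, abs=mu_w * 2 * small_grid.voxel_size)
        # exact value: the vertical LOR at x=0 sees one full pixel column
        col_x = small_grid.x_centers[small_grid.n_x // 2]
        n_in = int(np.sum(np.hypot(col_x, small_grid.y_centers) <= 5.0))
        assert sino.values[center, 0] == pytest.approx(
            mu_w * n_in * small_grid.voxel_size, rel=1e-12)
        a = np.exp(-sino.values)
        assert np.all((a > 0) & (a <= 1.0))


class TestValidation:
    def test_grid_beyond_fov_rejected(self, small_geom):
        big = ImageGrid(80, 80, 0.4)
        with pytest.raises(ValueError, match="field of view"):
            Projector(small_geom, big)

    def test_negative_activity_rejected(self, small_geom, small_grid, small_tof):
        lam = ActivityImage(np.full(small_grid.shape, -1.0), small_grid)
        with pytest.raises(ValueError, match="nonnegative"):
            forward_emission_tof(lam, small_geom, small_tof)
        with pytest.raises(ValueError, match="nonnegative"):
            forward_emission_nontof(lam, small_geom)

    def test_negative_attenuation_rejected(self, small_geom, small_grid):
        mu = AttenuationImage(np.full(small_grid.shape, -0.1), small_grid)
        with pytest.raises(ValueError, match="nonnegative"):
            forward_attenuation(mu, small_geom)

    def test_shape_mismatch_rejected(self, small_proj):
        with pytest.raises(ValueError, match="shape"):
            small_proj.forward(np.zeros((5, 5)))
        with pytest.raises(ValueError, match="shape"):
            small_proj.back(np.zeros((5, 5)))

    def test_tof_bins_must_cover_fov(self, small_geom, small_grid):
        narrow = TOFModel(n_tof_bins=3, tof_bin_width=1.0)
        with pytest.raises(ValueError, match="cover"):
            Projector(small_geom, small_grid, narrow)

    def test_geometry_invariants(self):
        with pytest.raises(ValueError):
            ScanGeometry(ring_diameter=30.0, fov_radius=20.0)
        with pytest.raises(ValueError):
            TOFModel(n_tof_bins=4)  # even


class TestReduced3D:
    def test_slice_stacked_projection_shapes(self, small_geom, small_tof):
        grid3 = ImageGrid(32, 32, 0.4, n_z=3)
        lam = ActivityImage(np.ones(grid3.shape), grid3)
        s = forward_emission_nontof(lam, small_geom)
        assert s.values.shape == (small_geom.n_radial, small_geom.n_angles, 3)
        st_ = forward_emission_tof(lam, small_geom, small_tof)
        assert st_.values.shape == (small_geom.n_radial, small_geom.n_angles, 3,
                                    small_tof.n_tof_bins)
        # each slice identical for a z-uniform image
        assert np.allclose(s.values[:, :, 0], s.values[:, :, 2])

    def test_tof_sinogram_marginalizes_to_sinogram(self, small_proj):
        rng = np.random.default_rng(2)
        x = rng.random(small_proj.grid.shape)
        yt = TOFSinogram(small_proj.forward_tof(x))
        assert np.allclose(yt.to_nontof().values, yt.values.sum(axis=-1))

    def test_coarse_grid_halves_dimensions(self, small_grid_fine):
        cg = coarse_grid(small_grid_fine)
        assert (cg.n_x, cg.n_y) == (32, 32)
        assert cg.voxel_size == pytest.approx(0.4)
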