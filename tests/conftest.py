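"""Shared fixtures: a small desk geometry for unit tests and the full
evaluation-phantom setup (built once per session) for end-to-end checks."""

import numpy as np
import pytest

from tofmlaa import (
    ActivityImage,
    ImageGrid,
    JointConfig,
    ScanGeometry,
    TOFModel,
    VOISpec,
    WATER_MU,
    build_phantom,
    compute_unit_medium,
    default_phantom,
    simulate_tof_counts,
    support_mask,
)
from tofmlaa.phantom_sim import Insert, PhantomSpec
from tofmlaa.scanner_model import get_projector


# --------------------------------------------------------------------------
# small geometry for fast unit tests

@pytest.fixture(scope="session")
def small_geom():
    return ScanGeometry(ring_diameter=30.0, n_radial=33, n_angles=24, fov_radius=6.4)


@pytest.fixture(scope="session")
def small_grid():
    return ImageGrid(32, 32, 0.4)


@pytest.fixture(scope="session")
def small_grid_fine():
    return ImageGrid(64, 64, 0.2)


@pytest.fixture(scope="session")
def small_tof():
    return TOFModel(timing_resolution_fwhm_ps=300.0, n_tof_bins=7, tof_bin_width=2.0)


@pytest.fixture(scope="session")
def small_proj(small_geom, small_grid, small_tof):
    return get_projector(small_geom, small_grid, small_tof)


@pytest.fixture(scope="session")
def small_proj_nontof(small_geom, small_grid):
    return get_projector(small_geom, small_grid)


@pytest.fixture(scope="session")
def small_proj_fine(small_geom, small_grid_fine, small_tof):
    return get_projector(small_geom, small_grid_fine, small_tof)


@pytest.fixture(scope="session")
def small_phantom():
    """A 10 cm water disk with one hot lesion and one lung-like insert."""
    return PhantomSpec(
        background_diameter=10.0,
        inserts=(
            Insert(center=(-2.0, -1.0), diameter=2.4, attenuation=WATER_MU / 3.0),
            Insert(center=(2.0, 1.5), diameter=2.0, activity_contrast=4.0),
        ),
        total_trues=2e5,
    )


@pytest.fixture(scope="session")
def small_images(small_phantom, small_grid_fine, small_grid):
    return build_phantom(small_phantom, small_grid_fine, small_grid)


# --------------------------------------------------------------------------
# full evaluation phantom (the study conditions); built once per session

class StudySetup:
    """Scanner, grids, phantom truth, unit medium and simulated data."""

    def __init__(self):
        self.geom = ScanGeometry()
        self.tof = TOFModel()
        self.act_grid = ImageGrid(192, 192, 0.2)
        self.att_grid = ImageGrid(96, 96, 0.4)
        self.spec = default_phantom()
        self.lam_true, self.mu_true = build_phantom(self.spec, self.act_grid, self.att_grid)
        self.sup_act = support_mask(self.spec, self.act_grid, margin=1.0)
        self.sup_att = support_mask(self.spec, self.att_grid, margin=1.0)
        self.obj_act = support_mask(self.spec, self.act_grid, margin=0.0)
        self.obj_att = support_mask(self.spec, self.att_grid, margin=0.0)
        self.proj_act = get_projector(self.geom, self.act_grid, self.tof)
        self.proj_att = get_projector(self.geom, self.att_grid)
        self.unit = compute_unit_medium(self.proj_att, self.obj_att)
        self.voi1 = VOISpec.disk(self.att_grid, (5.0, -5.0), 12.0, WATER_MU)
        self.voi2 = VOISpec.disk(self.att_grid, (0.0, 0.0), 6.0, WATER_MU)
        self.voi3 = VOISpec.disk(self.att_grid, (-4.0, 10.0), 8.0, WATER_MU)
        self.sim = simulate_tof_counts(self.lam_true, self.mu_true, None,
                                       self.spec.total_trues, seed=1,
                                       geometry=self.geom, tof=self.tof)
        self.truth = ActivityImage(self.sim.trues_scale * self.lam_true.values,
                                   self.act_grid)

    def joint_config(self, **kw):
        kw.setdefault("voi", self.voi1)
        return JointConfig(**kw)


@pytest.fixture(scope="session")
def study():
    return StudySetup()
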