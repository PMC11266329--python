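"""Shared fixtures: small grids and phantoms sized for fast unit tests."""

import dataclasses

import numpy as np
import pytest

from petmrac import (
    PhantomSpec,
    ReconSettings,
    ScanGeometry,
    default_spec,
    generate_patient,
)
from petmrac.phantoms import BodyGeometry, LesionSpec
from petmrac.pipeline import RunConfig


@pytest.fixture(scope="session")
def small_geometry() -> ScanGeometry:
    """32 angles x 96 bins covers a 64x64 grid at 3 mm pixels."""
    return ScanGeometry(n_angles=32, n_radial_bins=96, radial_spacing_mm=3.0)


@pytest.fixture(scope="session")
def small_settings() -> ReconSettings:
    return ReconSettings(iterations=4, subsets=16, postfilter_fwhm_mm=5.0)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Compact pelvic phantom: one primary + one nodal lesion, small grid."""
    return dataclasses.replace(
        default_spec(),
        grid_shape=(64, 64, 7),
        voxel_spacing_mm=(3.0, 3.0, 3.0),
        body_geometry=BodyGeometry(85.0, 70.0, 2.5, 6.0),
        bone_sites=(
            dataclasses.replace(default_spec().bone_sites[0], center_mm=(-50.0, 5.0), radius_mm=14.0),
            dataclasses.replace(default_spec().bone_sites[2], center_mm=(0.0, 40.0), radius_mm=12.0),
        ),
        lesion_specs=(
            LesionSpec((0.0, -10.0, 0.0), 18.0, 8.0, "primary"),
            LesionSpec((40.0, -20.0, 0.0), 12.0, 6.0, "nodal"),
        ),
        air_pockets=(),
    )


@pytest.fixture(scope="session")
def small_patient(small_spec):
    return generate_patient(small_spec, seed=7)


@pytest.fixture(scope="session")
def uniform_disc():
    """Antialiased uniform disc (radius 60 mm) on a 64x64 grid at 3 mm."""
    n, pix, r = 64, 3.0, 60.0
    c = (n - 1) / 2.0
    xx, yy = np.meshgrid((np.arange(n) - c) * pix, (np.arange(n) - c) * pix, indexing="ij")
    dist = np.sqrt(xx**2 + yy**2)
    img = np.clip((r - dist) / pix + 0.5, 0.0, 1.0)
    return img, dist, r, pix


def make_small_run_config(tmp_outdir=None, **overrides) -> RunConfig:
    """2-patient, 64^2 x 5 slice config for end-to-end pipeline tests."""
    cfg = RunConfig()
    cfg.cohort.n_patients = 2
    cfg.cohort.n_primary = 2
    cfg.cohort.n_nodal = 2
    cfg.cohort.grid_shape = (64, 64, 5)
    cfg.cohort.body_scale = 0.55
    cfg.acquisition.n_angles = 32
    cfg.acquisition.n_radial_bins = 96
    cfg.seed = 11
    if tmp_outdir is not None:
        cfg.outdir = str(tmp_outdir)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg
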