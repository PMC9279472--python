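"""Shared fixtures: small phantoms and a measurement helper.

Test phantoms use a reduced field of view (48 x 32 x 60 mm at 0.5 mm
isotropic) so the suite stays fast; the acceptance tests use the package's
full-size default geometry.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest

from varusscd import (PhantomSpec, apply_lateral_exclusion, build_frame,
                      build_grid, compute_scd_map, extract_surfaces,
                      generate_flat_plate, generate_knee_like,
                      transepicondylar_axis)

SMALL = PhantomSpec(volume_shape=(96, 64, 132), spacing_mm=(0.5, 0.5, 0.5),
                    femur_width_mm=40.0, tibia_width_mm=44.0,
                    shaft_width_mm=20.0, joint_z_mm=34.0)
SMALL_KNEE = dataclasses.replace(SMALL, condyle_radius_mm=25.0)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return SMALL


@pytest.fixture(scope="session")
def small_knee_spec() -> PhantomSpec:
    return SMALL_KNEE


@pytest.fixture(scope="session")
def flat_volume():
    return generate_flat_plate(SMALL)


@pytest.fixture(scope="session")
def knee_volume():
    return generate_knee_like(SMALL_KNEE)


def measure_volume(volume, baseline=None, exclusion=0.10):
    """Run the measurement chain on one volume against a baseline.

    Returns (scd_map, grid, frame, surfaces-of-volume).
    """
    base = volume if baseline is None else baseline
    fr = build_frame(base)
    te = transepicondylar_axis(base, fr)
    surf0 = extract_surfaces(base, fr)
    grid = apply_lateral_exclusion(build_grid(surf0), te, exclusion)
    surf = surf0 if baseline is None else extract_surfaces(volume, fr)
    smap = compute_scd_map(surf, grid)
    return smap, grid, fr, surf


@pytest.fixture(scope="session")
def measure():
    return measure_volume


def brute_force_column_gaps(volume, stride=4):
    """Independent per-column gap oracle: explicit python loops over voxels.

    Gap = (bottom boundary of lowest femur voxel above the tibia) - (top
    boundary of the highest tibia voxel); NaN where either bone is absent.
    Subsampled by ``stride`` in x and y for speed.
    """
    vox = volume.voxels
    dz = volume.spacing_mm[2]
    nx, ny, nz = vox.shape
    out = {}
    for i in range(0, nx, stride):
        for j in range(0, ny, stride):
            col = vox[i, j, :]
            t_top = None
            for k in range(nz - 1, -1, -1):
                if col[k] in (2, 3):
                    t_top = k
                    break
            if t_top is None:
                continue
            f_bot = None
            for k in range(t_top + 1, nz):
                if col[k] == 1:
                    f_bot = k
                    break
            if f_bot is None:
                continue
            out[(i, j)] = (f_bot - t_top - 1) * dz
    return out
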