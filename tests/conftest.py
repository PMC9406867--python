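"""Shared fixtures: expensive solves are session-scoped so each runs once."""

from __future__ import annotations

import numpy as np
import pytest

from implantheat.fixtures import make_implant
from implantheat.gc import solve_unit_current
from implantheat.sequence import Axis
from implantheat.voxel import VoxelField

SPHERE_RADIUS = 0.012  # m
SPHERE_SPACING = 1e-3  # 24 voxels across the diameter


@pytest.fixture(scope="session")
def sphere_implant():
    return make_implant("sphere", {"radius": SPHERE_RADIUS}, spacing=SPHERE_SPACING)


@pytest.fixture(scope="session")
def sphere_unit_solutions(sphere_implant):
    return {ax: solve_unit_current(sphere_implant, ax) for ax in Axis}


@pytest.fixture(scope="session")
def sphere_steady_solution(sphere_implant):
    """Steady unit-power heating of the sphere with a spherical zero-rise
    shell at R = 4a (finite-domain closed form available)."""
    from implantheat.thermal import ThermalParams, steady_state

    a = SPHERE_RADIUS
    params = ThermalParams(perfusion_coefficient=0.0, implant_perfusion=0.0)
    R = 4 * a
    ss = steady_state(
        sphere_implant,
        params,
        boundary="dirichlet",
        pad=3.2 * a,
        fixed_zero_outside_radius=R,
    )
    return a, R, params, ss


@pytest.fixture
def uniform_grid():
    """Small uniform voxel-field factory sharing one grid."""
    dims = (10, 10, 11)
    spacing = (0.01, 0.01, 0.01)
    origin = tuple(-(n - 1) * 0.01 / 2.0 for n in dims)

    def make(values, kind="generic"):
        arr = np.broadcast_to(np.asarray(values), dims).copy()
        return VoxelField(arr, spacing, origin, kind=kind)

    return make
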