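"""Shared geometric fixtures: analytic solids with known measures."""

import numpy as np
import pytest
import trimesh

from airwaymorph import PhantomSpec, generate_phantom
from airwaymorph.mesh_io import AirwayMesh


def cylinder_spec(radius=5.0, length=40.0, n_theta=128, axial_step=1.0):
    """Constant-radius tube phantom: volume pi r^2 L, lateral area 2 pi r L."""
    return PhantomSpec(
        segment_lengths={"OP": length, "NP": 0.001, "NS": 0.001},
        profile_knots=((-5.0, radius), (length + 5.0, radius)),
        n_theta=n_theta,
        axial_step=axial_step,
        inferior_margin=0.0,
    )


def hourglass_spec(r_outer=8.0, r_neck=3.0, length=60.0, n_theta=128):
    """Tube with a smooth narrow waist at the center."""
    knots = (
        (-5.0, r_outer), (0.0, r_outer), (length * 0.25, r_outer),
        (length * 0.5, r_neck), (length * 0.75, r_outer), (length + 5.0, r_outer),
    )
    return PhantomSpec(
        segment_lengths={"OP": length, "NP": 0.001, "NS": 0.001},
        profile_knots=knots,
        n_theta=n_theta,
        axial_step=0.75,
        inferior_margin=0.0,
    )


@pytest.fixture(scope="session")
def cylinder():
    mesh, truth = generate_phantom(cylinder_spec())
    return mesh, truth


@pytest.fixture(scope="session")
def hourglass():
    mesh, truth = generate_phantom(hourglass_spec())
    return mesh, truth


@pytest.fixture(scope="session")
def icosphere10():
    """Icosphere of radius 10 mm, 4 subdivisions."""
    tm = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
    return AirwayMesh.from_trimesh(tm)


@pytest.fixture(scope="session")
def default_phantom():
    mesh, truth = generate_phantom(PhantomSpec(n_theta=64, axial_step=1.5))
    return mesh, truth


@pytest.fixture()
def tetrahedron():
    verts = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    m = AirwayMesh(verts, faces)
    m.closed = True
    return m
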