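import numpy as np
import pytest

from seedmech import curvature as curv
from seedmech import shell
from seedmech import synthetic as syn
from seedmech.mesh import EllipsoidSpec


@pytest.fixture(scope="session")
def material():
    return shell.ShellMaterial()


@pytest.fixture(scope="session")
def sphere4():
    """Refinement-4 sphere of radius 100 µm (5120 faces)."""
    return syn.make_ellipsoid_mesh(EllipsoidSpec.sphere(100.0), 4)


@pytest.fixture(scope="session")
def sphere4_tess(sphere4):
    return syn.tessellate_surface(sphere4, 60, rng_seed=11)


@pytest.fixture(scope="session")
def sphere4_stress(sphere4, material):
    """Per-face membrane stress on the refinement-4 sphere."""
    return shell.solve_membrane_stress(sphere4, material)


@pytest.fixture(scope="session")
def spheroid4(material):
    """Prolate spheroid a=170, b=c=100 at refinement 4, with per-face stress."""
    mesh = syn.make_ellipsoid_mesh(EllipsoidSpec(170.0, 100.0, 100.0), 4)
    field = shell.solve_membrane_stress(mesh, material)
    return mesh, field


@pytest.fixture(scope="session")
def twodpa_prediction(material):
    """Inflated-shell model prediction on the 2DPA seed spec.

    The seed-ratio ellipsoid is the unloaded reference; stress and
    curvature are evaluated on the pressurized equilibrium shape.
    """
    spec = EllipsoidSpec.two_dpa_seed()
    mesh = syn.make_ellipsoid_mesh(spec, 4)
    tess = syn.tessellate_surface(mesh, 200, rng_seed=21)
    shape = shell.inflate_shell(mesh, material)
    tess_shape = type(tess)(shape, tess.face_cell)
    stress = shell.solve_membrane_stress(shape, material, tess_shape)
    curvature = curv.estimate_curvature(shape, tess_shape, 30.0)
    labels = shell.classify_regions(mesh, tess, spec)
    return {
        "spec": spec,
        "mesh": mesh,
        "tess": tess,
        "shape": shape,
        "stress": stress,
        "curvature": curvature,
        "labels": labels,
    }


@pytest.fixture(scope="session")
def twodpa_1000cells():
    """2DPA ellipsoid with a 1000-cell tessellation and its curvature field."""
    spec = EllipsoidSpec.two_dpa_seed()
    mesh = syn.make_ellipsoid_mesh(spec, 4)
    tess = syn.tessellate_surface(mesh, 1000, rng_seed=7)
    curvature = curv.estimate_curvature(mesh, tess, 30.0)
    return mesh, tess, curvature
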