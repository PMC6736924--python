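"""Shared fixtures: phantoms at several sizes and common meshes.

Session scope keeps the expensive phantom builds to one per run; tests
must not mutate fixture objects (copy first).
"""

from __future__ import annotations

import numpy as np
import pytest
import trimesh
from hypothesis import settings

from pneumosim.imaging import SurfaceMesh
from pneumosim.phantom import PhantomSpec, generate_phantom

settings.register_profile("suite", deadline=None, max_examples=25,
                          derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_pair():
    """The default phantom (used by imaging-chain tests)."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def small_spec():
    """Half-scale phantom spec sized for simulation tests
    (~1,300 particles at radius 2.7)."""
    return PhantomSpec(skin_semi_axes=(18.0, 14.0, 15.0), wall_thickness=2.0,
                       viscera_semi_axes=(14.75, 10.75, 11.75),
                       gap_thickness=1.25, mesh_subdivisions=3,
                       bump_amplitude=3.0)


@pytest.fixture(scope="session")
def small_pair(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def tiny_spec():
    """Very small phantom (~300–500 particles) for long-running and
    parameter-corner simulations."""
    return PhantomSpec(skin_semi_axes=(12.0, 9.0, 10.0), wall_thickness=2.0,
                       viscera_semi_axes=(8.6, 5.6, 6.6), gap_thickness=1.2,
                       mesh_subdivisions=2, bump_amplitude=2.0)


@pytest.fixture(scope="session")
def tiny_pair(tiny_spec):
    return generate_phantom(tiny_spec)


@pytest.fixture()
def icosphere30():
    ico = trimesh.creation.icosphere(subdivisions=3, radius=30.0)
    return SurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces),
                       "inflatable")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
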