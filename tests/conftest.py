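"""Shared fixtures: synthetic worlds at two scales.

The small world (160 vertices, n=120) keeps unit tests fast; the full-size
world (500 vertices, n=500, seed 0) is shared by the parameter-recovery and
end-to-end assessments so the expensive build runs once per session.
"""

import numpy as np
import pytest

from facegrowth import GenerativeSpec, build_growth_curves, simulate_cohort
from facegrowth.regression import KernelConfig
from facegrowth.simulate import base_topology


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_spec():
    return GenerativeSpec(n_vertices=160, seed=3)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    shapes, table = simulate_cohort(small_spec, 120, seed=11, sex="female")
    return shapes, table


@pytest.fixture(scope="session")
def small_model(small_spec, small_cohort):
    shapes, _ = small_cohort
    return build_growth_curves(
        shapes,
        base_topology(small_spec),
        sex="female",
        age_grid=np.array([20.0, 30.0]),
        kernel=KernelConfig(sigma_floor=1.0, min_effective_n=40),
        retained_fraction=0.98,
    )


@pytest.fixture(scope="session")
def full_spec():
    return GenerativeSpec()


@pytest.fixture(scope="session")
def full_cohort(full_spec):
    shapes, table = simulate_cohort(full_spec, 500, seed=0, sex="female")
    return shapes, table


@pytest.fixture(scope="session")
def full_model(full_spec, full_cohort):
    shapes, _ = full_cohort
    return build_growth_curves(
        shapes,
        base_topology(full_spec),
        sex="female",
        age_grid=np.array([25.0, 30.0, 35.0]),
        kernel=KernelConfig(sigma_floor=1.0, min_effective_n=150),
        retained_fraction=0.98,
    )


@pytest.fixture()
def tetrahedron():
    vertices = np.array(
        [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
    )
    triangles = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
    return vertices, triangles


def random_rigid(rng, max_angle=np.pi):
    """A random proper rotation + translation."""
    from scipy.spatial.transform import Rotation

    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(-max_angle, max_angle)
    R = Rotation.from_rotvec(angle * axis).as_matrix()
    t = rng.standard_normal(3) * 20.0
    return R, t
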