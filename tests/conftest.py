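import numpy as np
import pytest

from shell_lattice.geometry import matrix_to_euler, random_rotations
from shell_lattice.io_formats import ParticleTable
from shell_lattice.synthetic import SurfaceSpec, decorate_lattice, make_surface


@pytest.fixture(scope="session")
def plane_mesh():
    """1150 × 1150 Å plane: fits an 11 × 11 lattice of 115 Å tiles exactly."""
    return make_surface(SurfaceSpec(kind="plane", size=(1150.0, 1150.0), resolution=50.0))


@pytest.fixture(scope="session")
def sphere_mesh():
    return make_surface(SurfaceSpec(kind="sphere", size=(800.0,), resolution=40.0))


@pytest.fixture(scope="session")
def plane_p4():
    mesh = make_surface(SurfaceSpec(kind="plane", size=(1150.0, 1150.0), resolution=50.0))
    return decorate_lattice(mesh, group="p4", a=115.0)


@pytest.fixture(scope="session")
def sphere_p4(sphere_mesh):
    return decorate_lattice(sphere_mesh, group="p4", a=115.0, min_dist_frac=0.9)


def random_table(n: int, seed: int, box: float = 1000.0, scores: bool = True) -> ParticleTable:
    rng = np.random.default_rng(seed)
    return ParticleTable(
        ids=np.arange(n),
        tomo_id=np.array([f"tomo_{i % 3}" for i in range(n)], dtype=object),
        positions=rng.uniform(0.0, box, (n, 3)),
        eulers=matrix_to_euler(random_rotations(n, rng)),
        scores=rng.uniform(0.0, 1.0, n) if scores else None,
    )
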