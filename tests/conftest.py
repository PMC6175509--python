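"""Shared fixtures: sphere/ellipsoid clouds, phantoms, reconstructed surfaces.

Expensive objects (Poisson meshes, the default phantom, the full
pipeline run) are session-scoped so the suite builds them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from scarmesh.phantom import PhantomSpec, generate_phantom
from scarmesh.surface import estimate_normals, poisson_reconstruct
from scarmesh.volume import BinaryMask, LGEVolume

SPHERE_R_ENDO = 20.0
SPHERE_R_EPI = 30.0


def unit_sphere_points(n: int, seed: int = 1) -> np.ndarray:
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


@pytest.fixture(scope="session")
def sphere_cloud():
    """2000 points on a 20 mm sphere."""
    return SPHERE_R_ENDO * unit_sphere_points(2000)


@pytest.fixture(scope="session")
def sphere_mesh(sphere_cloud):
    return poisson_reconstruct(estimate_normals(sphere_cloud, k=10), depth=7)


@pytest.fixture(scope="session")
def concentric_sphere_setup():
    """Endo/epi sphere meshes (20 / 30 mm) plus a 1 mm shell mask."""
    endo = poisson_reconstruct(
        estimate_normals(SPHERE_R_ENDO * unit_sphere_points(3000, seed=2), k=10),
        depth=7,
    )
    epi = poisson_reconstruct(
        estimate_normals(SPHERE_R_EPI * unit_sphere_points(3000, seed=3), k=10),
        depth=7,
    )
    n = 72
    affine = np.diag([1.0, 1.0, 1.0, 1.0])
    affine[:3, 3] = -(n - 1) / 2.0
    grid = LGEVolume(np.zeros((n, n, n)), (1.0, 1.0, 1.0), affine)
    centers = grid.voxel_centers().reshape(-1, 3)
    r = np.linalg.norm(centers, axis=1)
    shell = ((r >= SPHERE_R_ENDO) & (r <= SPHERE_R_EPI)).reshape(n, n, n)
    myocardium = BinaryMask(shell, grid)
    from scarmesh.segmentation import transmural_depth_field

    depth = transmural_depth_field(myocardium, endo, epi)
    return {
        "endo": endo,
        "epi": epi,
        "grid": grid,
        "centers": centers,
        "radius": r,
        "myocardium": myocardium,
        "depth": depth,
    }


@pytest.fixture(scope="session")
def default_phantom():
    """The standard 1 mm phantom with one anterior scar blob."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def pipeline_result(default_phantom):
    from scarmesh.pipeline import run_pipeline

    return run_pipeline(default_phantom.volume, default_phantom.contours)
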