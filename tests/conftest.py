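"""Shared fixtures: meshes and solves are expensive, so they are built once
per session and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import ttfsim
from ttfsim import meshing, solver
from ttfsim.electrodes import Electrode, ElectrodeConfiguration
from ttfsim.tissues import TISSUE_IDS

HOMOGENEOUS_RADIUS = 92.0
HOMOGENEOUS_SIGMA = 0.3


@pytest.fixture(scope="session")
def homogeneous_mesh():
    """Default-resolution homogeneous sphere (R = 92 mm, sigma = 0.3 S/m)."""
    mesh = ttfsim.build_layered_sphere_mesh(
        (HOMOGENEOUS_RADIUS,), resolution=7.0, layer_labels=("gm",)
    )
    table = ttfsim.TissueConductivityTable.default().overridden(gm=HOMOGENEOUS_SIGMA)
    return ttfsim.assign_conductivity(mesh, table)


@pytest.fixture(scope="session")
def homogeneous_system(homogeneous_mesh):
    return solver.StiffnessSystem(homogeneous_mesh)


@pytest.fixture(scope="session")
def antipodal_pair():
    R = HOMOGENEOUS_RADIUS
    src = Electrode(0, (0.0, R, 0.0))
    snk = Electrode(1, (0.0, -R, 0.0))
    return ElectrodeConfiguration((src, snk), (1.0, -1.0), "antipodal")


@pytest.fixture(scope="session")
def homogeneous_solution(homogeneous_system, antipodal_pair):
    return solver.solve_configuration(homogeneous_system, antipodal_pair, 1.0)


@pytest.fixture(scope="session")
def layered_mesh():
    """Four-layer head (skin, compact skull, CSF, brain), moderate resolution."""
    return ttfsim.build_layered_sphere_mesh((92.0, 86.0, 80.0, 78.0), resolution=8.0)


@pytest.fixture(scope="session")
def coarse_intracranial():
    """Small stripped head with conductivities, for superposition tests."""
    mesh = ttfsim.build_layered_sphere_mesh(
        (92.0, 86.0, 80.0, 78.0, 60.0), resolution=11.0
    )
    mesh = ttfsim.assign_conductivity(mesh)
    return ttfsim.strip_to_intracranial(mesh)


@pytest.fixture(scope="session")
def coarse_intracranial_system(coarse_intracranial):
    return solver.StiffnessSystem(coarse_intracranial)


def build_mirror_symmetric_ball(radius: float = 92.0, resolution: float = 9.0):
    """Homogeneous ball whose node set is mirror-symmetric about x = 0,
    so the discrete solution of an antipodal y-axis pair should be too."""
    from scipy.spatial import Delaunay

    pts = []
    for r in np.arange(radius, 0, -resolution):
        n = max(8, int(round(4 * np.pi * r**2 / resolution**2)))
        sh = meshing.fibonacci_sphere(n, r, phase=0.3)
        half = sh[sh[:, 0] > 0.3]
        onplane = sh[np.abs(sh[:, 0]) <= 0.3].copy()
        onplane[:, 0] = 0.0
        pts += [half, half * np.array([-1.0, 1.0, 1.0]), onplane]
    pts.append(np.zeros((1, 3)))
    pts = np.concatenate(pts)
    _, uniq = np.unique(np.round(pts / 1e-6).astype(np.int64), axis=0, return_index=True)
    pts = pts[np.sort(uniq)]
    tri = Delaunay(pts)
    elements = tri.simplices.astype(np.int64)
    p = pts[elements]
    det = np.linalg.det(p[:, 1:] - p[:, :1])
    elements[det < 0] = elements[det < 0][:, [0, 1, 3, 2]]
    elements = elements[np.abs(det) / 6.0 > 1e-9 * resolution**3]
    mesh = meshing.HeadMesh(
        nodes=pts,
        elements=elements,
        labels=np.full(len(elements), TISSUE_IDS["gm"], dtype=np.int32),
    )
    return ttfsim.assign_conductivity(mesh)


def interior_probes(
    n: int,
    seed: int,
    radius: float = HOMOGENEOUS_RADIUS,
    keepout_points=(),
    keepout_mm: float = 25.0,
    max_fraction: float = 0.7,
) -> np.ndarray:
    """Deterministic interior probe points away from the given electrodes."""
    rng = np.random.default_rng(seed)
    probes = []
    while len(probes) < n:
        p = rng.uniform(-max_fraction * radius, max_fraction * radius, 3)
        if np.linalg.norm(p) > max_fraction * radius:
            continue
        if any(np.linalg.norm(p - np.asarray(q)) < keepout_mm for q in keepout_points):
            continue
        probes.append(p)
    return np.asarray(probes)
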