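"""Quasistatic finite-element forward solver and lead-field superposition.

The conduction (quasistatic) approximation reduces Maxwell's equations to
the generalized Laplace problem div(sigma grad phi) = 0 in the head, with
Neumann boundary conditions: a uniform inward current density over each
electrode footprint on the outer surface, zero flux elsewhere. Piecewise
linear (P1) tetrahedral elements give a constant electric field
E = -grad(phi) per element.

The pure Neumann problem fixes phi only up to a constant; the zero-mean
gauge is imposed with a Lagrange multiplier. The assembled operator is
factorized once (sparse LU) and reused for every right-hand side, which is
what makes the 101-electrode lead-field basis cheap: any electrode pair's
field is the difference of two unit-current basis solutions, scaled by the
injected current.

Lengths enter in mm and are converted to meters at assembly, so potentials
are in volts; fields are reported in V/cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .electrodes import Electrode, ElectrodeConfiguration
from .meshing import HeadMesh

MM_TO_M = 1e-3
V_PER_M_TO_V_PER_CM = 1e-2


class SolverError(RuntimeError):
    pass


class DegenerateElementError(SolverError):
    pass


class FootprintError(SolverError):
    """Electrode footprint empty or off the active boundary."""


@dataclass
class FieldSolution:
    """Solution of one stimulation pattern.

    potential : (n_nodes,) V, zero-mean gauge
    e_field : (n_elements, 3) V/cm, constant per element
    current : injected current I in A
    name : configuration provenance
    """

    potential: np.ndarray
    e_field: np.ndarray
    current: float
    name: str = ""

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.e_field, axis=1)

    def scaled(self, factor: float) -> "FieldSolution":
        return FieldSolution(
            potential=self.potential * factor,
            e_field=self.e_field * factor,
            current=self.current * factor,
            name=self.name,
        )


def _element_gradients(mesh: HeadMesh) -> Tuple[np.ndarray, np.ndarray]:
    """P1 basis gradients (m, 4, 3) in 1/m and element volumes (m,) in m^3."""
    p = mesh.nodes[mesh.elements] * MM_TO_M
    d = p[:, 1:] - p[:, :1]  # (m, 3, 3) rows = edge vectors
    det = np.linalg.det(d)
    vol = np.abs(det) / 6.0
    if (vol <= 1e-18).any():
        bad = int(np.argmin(vol))
        raise DegenerateElementError(
            f"element {bad} has near-zero volume {vol[bad]:.3e} m^3"
        )
    dinv = np.linalg.inv(d)  # columns are grads of barycentric coords 1..3
    g123 = np.transpose(dinv, (0, 2, 1))  # (m, 3 basis, 3 xyz)
    g0 = -g123.sum(axis=1, keepdims=True)
    grads = np.concatenate([g0, g123], axis=1)  # (m, 4, 3)
    return grads, vol


class StiffnessSystem:
    """Assembled FEM operator for one mesh, with a reusable factorization.

    The stiffness matrix K is symmetric positive-semidefinite with the
    constants in its null space (row sums are zero). Solves enforce the
    zero-mean potential gauge through a bordered (Lagrange-multiplier)
    system, factorized once with sparse LU.
    """

    def __init__(self, mesh: HeadMesh):
        if mesh.conductivity is None:
            raise SolverError("mesh has no conductivity tensors; run assign_conductivity")
        self.mesh = mesh
        self.grads, self.volumes_m3 = _element_gradients(mesh)
        n = len(mesh.nodes)
        # Ke[a,b] = V * grad_a . sigma . grad_b
        sg = np.einsum("eij,eaj->eai", mesh.conductivity, self.grads)
        ke = np.einsum("eai,ebi->eab", self.grads, sg) * self.volumes_m3[:, None, None]
        rows = np.repeat(mesh.elements, 4, axis=1).reshape(-1)
        cols = np.tile(mesh.elements, (1, 4)).reshape(-1)
        self.K = sp.coo_matrix(
            (ke.reshape(-1), (rows, cols)), shape=(n, n)
        ).tocsr()
        self._factor = None

    @property
    def n_nodes(self) -> int:
        return len(self.mesh.nodes)

    def _factorize(self):
        if self._factor is None:
            n = self.n_nodes
            c = np.full((n, 1), 1.0 / n)
            A = sp.bmat([[self.K, c], [c.T, None]], format="csc")
            self._factor = spla.splu(A)
        return self._factor

    def solve_potential(self, nodal_current: np.ndarray) -> np.ndarray:
        """Solve K phi = b with zero-mean gauge; b in A, phi in V."""
        b = np.asarray(nodal_current, dtype=float)
        if abs(b.sum()) > 1e-9 * max(np.abs(b).max(), 1e-30):
            raise SolverError(
                f"nodal currents must balance (sum {b.sum():.3e} A)"
            )
        rhs = np.concatenate([b - b.sum() / len(b), [0.0]])
        sol = self._factorize().solve(rhs)
        phi = sol[:-1]
        phi -= phi.mean()
        return phi

    def element_field(self, phi: np.ndarray) -> np.ndarray:
        """E = -grad(phi) per element, in V/cm."""
        phi_e = phi[self.mesh.elements]  # (m, 4)
        grad = np.einsum("ea,eai->ei", phi_e, self.grads)  # V/m
        return -grad * V_PER_M_TO_V_PER_CM


# ---------------------------------------------------------------------------
# electrode footprints and right-hand sides
# ---------------------------------------------------------------------------

def electrode_footprint(
    mesh: HeadMesh, electrode: Electrode
) -> Tuple[np.ndarray, np.ndarray]:
    """Boundary triangles under an electrode and their areas (mm^2).

    Triangles whose centroid lies within the electrode radius (chordal
    distance) of the electrode center projected on the surface; if the mesh
    is too coarse for any centroid to qualify, the single nearest boundary
    triangle is used so the footprint is never empty.
    """
    centers = mesh.boundary_face_centroids()
    areas = mesh.boundary_face_areas()
    p = electrode.position()
    R = mesh.outer_radius()
    p = p * (R / np.linalg.norm(p))
    d = np.linalg.norm(centers - p, axis=1)
    sel = np.flatnonzero(d <= electrode.radius)
    if sel.size == 0:
        sel = np.array([int(np.argmin(d))])
    return sel, areas[sel]


def configuration_rhs(
    mesh: HeadMesh, config: ElectrodeConfiguration, current: float
) -> np.ndarray:
    """Nodal current vector (A) for uniform current density per footprint."""
    faces, _ = mesh.boundary_triangles()
    b = np.zeros(len(mesh.nodes))
    for elec, share in zip(config.electrodes, config.currents):
        tri_idx, areas = electrode_footprint(mesh, elec)
        total = areas.sum()
        if total <= 0:
            raise FootprintError(f"electrode {elec.id} has empty footprint")
        tri_current = current * share * areas / total
        np.add.at(b, faces[tri_idx].ravel(), np.repeat(tri_current / 3.0, 3))
    return b


def solve_configuration(
    system: StiffnessSystem,
    config: ElectrodeConfiguration,
    current: float = 1.0,
) -> FieldSolution:
    """Direct solve of one stimulation pattern at injected current I (A)."""
    if current < 0:
        raise SolverError("injected current must be non-negative")
    if current == 0.0:
        n = system.n_nodes
        m = len(system.mesh.elements)
        return FieldSolution(np.zeros(n), np.zeros((m, 3)), 0.0, config.name)
    b = configuration_rhs(system.mesh, config, current)
    phi = system.solve_potential(b)
    return FieldSolution(phi, system.element_field(phi), current, config.name)


def probe_field(
    mesh: HeadMesh,
    solution: FieldSolution,
    points: np.ndarray,
    radius: Optional[float] = None,
) -> np.ndarray:
    """Field vectors (V/cm) at interior probe points.

    The P1 solution has a piecewise-constant field, so a point probe is
    evaluated as the volume-weighted average of the element fields within
    ``radius`` of the point (default: ~1.2 mean edge lengths), falling back
    to the nearest element when the ball is empty.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    centroids = mesh.element_centroids()
    vols = mesh.element_volumes()
    if radius is None:
        # mean edge length from mean element volume (regular-tet estimate)
        h = (vols.mean() * 6.0 * 2.0**0.5) ** (1.0 / 3.0)
        radius = 1.2 * h
    out = np.empty((len(points), 3))
    for k, p in enumerate(points):
        d = np.linalg.norm(centroids - p, axis=1)
        sel = d <= radius
        if not sel.any():
            sel = np.array([int(np.argmin(d))])
        out[k] = np.average(solution.e_field[sel], axis=0, weights=vols[sel])
    return out


# ---------------------------------------------------------------------------
# lead field
# ---------------------------------------------------------------------------

@dataclass
class LeadFieldBasis:
    """Unit-current solutions (electrode i vs reference) for superposition.

    potentials : (n_electrodes, n_nodes) V at 1 A
    e_fields : (n_electrodes, n_elements, 3) V/cm at 1 A
    electrode_ids : stimulation electrode ids, index-aligned with the arrays
    """

    electrode_ids: List[int]
    potentials: np.ndarray
    e_fields: np.ndarray
    reference_id: int

    _index: Dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {eid: k for k, eid in enumerate(self.electrode_ids)}

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_ids)

    def combine_pair(self, i: int, j: int, current: float = 1.0) -> FieldSolution:
        """Field of pair (i source, j sink) at current I by superposition:
        E(i, j; I) = I * (E_i - E_j). No linear solve is performed."""
        if i == j:
            raise ValueError("source and sink electrodes must differ")
        try:
            ki, kj = self._index[i], self._index[j]
        except KeyError as exc:
            raise KeyError(f"electrode {exc.args[0]} not in lead-field basis") from None
        return FieldSolution(
            potential=current * (self.potentials[ki] - self.potentials[kj]),
            e_field=current * (self.e_fields[ki] - self.e_fields[kj]),
            current=current,
            name=f"pair_{i}_{j}",
        )

    def unit_pair_magnitude(self, i: int, j: int) -> np.ndarray:
        """|E| per element (V/cm) for pair (i, j) at 1 A, without copies of
        the potential; used by the current sweeps."""
        ki, kj = self._index[i], self._index[j]
        diff = self.e_fields[ki] - self.e_fields[kj]
        return np.linalg.norm(diff, axis=1)


def build_lead_field(
    system: StiffnessSystem, electrodes: Sequence[Electrode]
) -> LeadFieldBasis:
    """Solve (electrode i, reference) at 1 A for every stimulation electrode."""
    refs = [e for e in electrodes if e.role == "reference"]
    if len(refs) != 1:
        raise SolverError(f"exactly one reference electrode required, got {len(refs)}")
    ref = refs[0]
    stim = sorted((e for e in electrodes if e.role == "stimulation"), key=lambda e: e.id)
    if not stim:
        raise SolverError("no stimulation electrodes")

    n, m = system.n_nodes, len(system.mesh.elements)
    potentials = np.empty((len(stim), n))
    e_fields = np.empty((len(stim), m, 3))
    for k, e in enumerate(stim):
        config = ElectrodeConfiguration(
            electrodes=(e, ref), currents=(1.0, -1.0), name=f"lead_{e.id}"
        )
        try:
            sol = solve_configuration(system, config, 1.0)
        except SolverError as exc:
            raise SolverError(f"lead-field solve failed for electrode {e.id}: {exc}")
        potentials[k] = sol.potential
        e_fields[k] = sol.e_field
    return LeadFieldBasis(
        electrode_ids=[e.id for e in stim],
        potentials=potentials,
        e_fields=e_fields,
        reference_id=ref.id,
    )
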