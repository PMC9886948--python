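"""Synthetic layered-sphere head meshes with embedded tumors.

The head is modeled as nested spherical compartments (skin, skull, CSF,
brain) meshed with linear tetrahedra. Node shells are placed exactly on
every compartment interface so that compartment boundaries are conforming;
the interior is filled with additional Fibonacci-lattice shells and
tetrahedralized with a Delaunay triangulation (the domain is convex, so the
Delaunay tetrahedra tile it exactly).

Coordinates are in mm, head frame: origin at the sphere center, +z superior,
+y anterior, +x right. Conductivities are in S/m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import Delaunay

from .tissues import (
    BRAIN_LABELS,
    ID_TO_TISSUE,
    INTRACRANIAL_LABELS,
    TISSUE_IDS,
    TUMOR_LABELS,
    TissueConductivityTable,
)


class InvalidGeometryError(ValueError):
    """Raised for inconsistent layer radii or tumor specifications."""


class MeshingError(RuntimeError):
    """Raised when a mesh cannot be generated at the requested resolution."""


#: Default compartment labels by number of layers (outer -> inner).
_DEFAULT_LAYER_LABELS: Dict[int, Tuple[str, ...]] = {
    1: ("gm",),
    2: ("csf", "gm"),
    3: ("skull_compact", "csf", "gm"),
    4: ("skin", "skull_compact", "csf", "gm"),
    5: ("skin", "skull_compact", "csf", "gm", "wm"),
    7: (
        "skin",
        "skull_compact",
        "skull_spongy",
        "skull_compact",
        "csf",
        "gm",
        "wm",
    ),
}

#: Adult-head-scale default: skin 92-86, compact skull 86-80, CSF 80-78,
#: GM 78-60, WM inside 60 mm.
DEFAULT_LAYER_RADII = (92.0, 86.0, 80.0, 78.0, 60.0)

#: Variant with a spongy-bone sublayer sandwiched in the skull (84.5-81.5 mm).
SPONGY_LAYER_RADII = (92.0, 86.0, 84.5, 81.5, 80.0, 78.0, 60.0)

DEFAULT_RESOLUTION_MM = 7.0


@dataclass(frozen=True)
class TumorSpec:
    """Spherical tumor: shell, optional nested core, optional resection cavity.

    Radii must be strictly decreasing (shell > core > resection, for the
    parts present). The whole tumor must sit inside brain tissue (GM/WM).
    """

    center: Tuple[float, float, float]
    shell_radius: float
    core_radius: Optional[float] = None
    resection_radius: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        if len(self.center) != 3:
            raise InvalidGeometryError("tumor center must have 3 coordinates")
        if self.shell_radius <= 0:
            raise InvalidGeometryError("tumor shell radius must be positive")
        nested = [self.shell_radius]
        for r in (self.core_radius, self.resection_radius):
            if r is not None:
                if r <= 0:
                    raise InvalidGeometryError("tumor radii must be positive")
                nested.append(r)
        if any(b >= a for a, b in zip(nested, nested[1:])):
            raise InvalidGeometryError(
                f"tumor radii must be strictly decreasing, got {nested}"
            )

    @property
    def nested_parts(self) -> List[Tuple[str, float]]:
        """(label, radius) from innermost to outermost part."""
        parts: List[Tuple[str, float]] = []
        if self.resection_radius is not None:
            parts.append(("resection", self.resection_radius))
        if self.core_radius is not None:
            parts.append(("tumor_core", self.core_radius))
        parts.append(("tumor_shell", self.shell_radius))
        return parts


@dataclass
class HeadMesh:
    """Labeled tetrahedral mesh with optional per-element conductivity tensors.

    Attributes
    ----------
    nodes : (n, 3) float array, mm
    elements : (m, 4) int array of node indices, positively oriented
    labels : (m,) int array of tissue ids (see :data:`ttfsim.tissues.TISSUE_IDS`)
    conductivity : (m, 3, 3) float array in S/m, or None before assignment
    layer_radii : interface radii of the spherical compartments, outer -> inner
    """

    nodes: np.ndarray
    elements: np.ndarray
    labels: np.ndarray
    conductivity: Optional[np.ndarray] = None
    layer_radii: Tuple[float, ...] = ()
    layer_labels: Tuple[str, ...] = ()
    _volumes: Optional[np.ndarray] = field(default=None, repr=False)
    _boundary: Optional[Tuple[np.ndarray, np.ndarray]] = field(default=None, repr=False)

    # -- geometry -----------------------------------------------------------
    def element_volumes(self) -> np.ndarray:
        """Per-element volume in mm^3 (always positive)."""
        if self._volumes is None:
            p = self.nodes[self.elements]
            d = p[:, 1:] - p[:, :1]
            self._volumes = np.abs(np.linalg.det(d)) / 6.0
        return self._volumes

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def total_volume(self) -> float:
        return float(self.element_volumes().sum())

    def label_volumes(self) -> Dict[str, float]:
        vols = self.element_volumes()
        out: Dict[str, float] = {}
        for lid in np.unique(self.labels):
            out[ID_TO_TISSUE[int(lid)]] = float(vols[self.labels == lid].sum())
        return out

    def label_names(self) -> List[str]:
        return sorted({ID_TO_TISSUE[int(l)] for l in np.unique(self.labels)})

    def elements_with_label(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.labels == TISSUE_IDS[label])

    # -- boundary -----------------------------------------------------------
    def boundary_triangles(self) -> Tuple[np.ndarray, np.ndarray]:
        """Outer-boundary triangles and their outward unit normals.

        Returns (faces, normals): faces (k, 3) node indices, normals (k, 3).
        A face is on the boundary iff it belongs to exactly one tetrahedron.
        """
        if self._boundary is None:
            tets = self.elements
            faces = np.concatenate(
                [
                    tets[:, [1, 2, 3]],
                    tets[:, [0, 2, 3]],
                    tets[:, [0, 1, 3]],
                    tets[:, [0, 1, 2]],
                ]
            )
            owner = np.tile(np.arange(len(tets)), 4)
            key = np.sort(faces, axis=1)
            _, idx, counts = np.unique(
                key, axis=0, return_index=True, return_counts=True
            )
            sel = idx[counts == 1]
            bfaces = faces[sel]
            bowner = owner[sel]
            # orient normals outward: away from the owning tet's centroid
            tri = self.nodes[bfaces]
            n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
            n /= np.linalg.norm(n, axis=1, keepdims=True)
            cen_tet = self.nodes[tets[bowner]].mean(axis=1)
            cen_tri = tri.mean(axis=1)
            flip = np.einsum("ij,ij->i", n, cen_tri - cen_tet) < 0
            n[flip] *= -1.0
            self._boundary = (bfaces, n)
        return self._boundary

    def boundary_face_centroids(self) -> np.ndarray:
        faces, _ = self.boundary_triangles()
        return self.nodes[faces].mean(axis=1)

    def boundary_face_areas(self) -> np.ndarray:
        faces, _ = self.boundary_triangles()
        tri = self.nodes[faces]
        return 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )

    def outer_radius(self) -> float:
        """Mean radius of the boundary nodes (the active surface radius)."""
        faces, _ = self.boundary_triangles()
        bn = np.unique(faces)
        return float(np.linalg.norm(self.nodes[bn], axis=1).mean())

    def copy(self) -> "HeadMesh":
        return HeadMesh(
            nodes=self.nodes.copy(),
            elements=self.elements.copy(),
            labels=self.labels.copy(),
            conductivity=None if self.conductivity is None else self.conductivity.copy(),
            layer_radii=self.layer_radii,
            layer_labels=self.layer_labels,
        )


# ---------------------------------------------------------------------------
# mesh generation
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int, radius: float, phase: float = 0.0) -> np.ndarray:
    """Deterministic quasi-uniform points on a sphere (Fibonacci lattice)."""
    i = np.arange(n, dtype=float)
    golden = (1.0 + 5.0**0.5) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = np.arccos(np.clip(z, -1, 1))
    phi = 2.0 * np.pi * (i / golden) + phase
    st = np.sin(theta)
    return radius * np.stack(
        [st * np.cos(phi), st * np.sin(phi), np.cos(theta)], axis=1
    )


def _shell_point_count(radius: float, spacing: float) -> int:
    return max(8, int(round(4.0 * np.pi * radius**2 / spacing**2)))


def _radial_stations(
    interface_radii: Sequence[float], resolution: float
) -> List[Tuple[float, bool]]:
    """Shell radii from outer surface to center; True marks interface shells."""
    radii = list(interface_radii)
    stations: List[Tuple[float, bool]] = []
    bounds = radii + [0.0]
    for outer, inner in zip(bounds[:-1], bounds[1:]):
        stations.append((outer, True))
        gap = outer - inner
        n_mid = int(np.floor(gap / resolution))
        if n_mid >= 1:
            mids = np.linspace(outer, inner, n_mid + 2)[1:-1]
            stations.extend((float(r), False) for r in mids)
    return stations


def build_layered_sphere_mesh(
    layer_radii: Sequence[float] = DEFAULT_LAYER_RADII,
    resolution: float = DEFAULT_RESOLUTION_MM,
    layer_labels: Optional[Sequence[str]] = None,
    refine_spheres: Optional[Sequence[Tuple[Sequence[float], float]]] = None,
    seed: int = 0,
) -> HeadMesh:
    """Generate a nested-sphere tetrahedral head mesh.

    Parameters
    ----------
    layer_radii : interface radii in mm, strictly decreasing outer -> inner.
        Layer k occupies radii (layer_radii[k], layer_radii[k+1]]; the
        innermost layer extends to the center.
    resolution : target edge length in mm.
    layer_labels : one tissue label per layer; defaults depend on the layer
        count (e.g. 4 layers -> skin, skull_compact, csf, gm). Repeated
        labels are allowed (compact/spongy/compact skull sandwich).
    refine_spheres : optional [(center, radius), ...] interior spherical
        interfaces (tumor boundaries) to resolve with conforming node shells.
    seed : decorrelates the azimuthal phase of successive shells.

    Raises
    ------
    InvalidGeometryError : radii not strictly decreasing / not positive.
    MeshingError : a declared layer receives no elements (resolution too
        coarse to resolve it), named in the message.
    """
    radii = [float(r) for r in layer_radii]
    if any(r <= 0 for r in radii):
        raise InvalidGeometryError("layer radii must be positive")
    if any(b >= a for a, b in zip(radii, radii[1:])):
        raise InvalidGeometryError(
            f"layer radii must be strictly decreasing, got {radii}"
        )
    if resolution <= 0:
        raise InvalidGeometryError("resolution must be positive")
    if resolution > radii[0]:
        raise MeshingError(
            f"resolution {resolution} mm exceeds the outer radius {radii[0]} mm"
        )

    if layer_labels is None:
        try:
            layer_labels = _DEFAULT_LAYER_LABELS[len(radii)]
        except KeyError:
            raise InvalidGeometryError(
                f"no default labels for {len(radii)} layers; pass layer_labels"
            ) from None
    layer_labels = tuple(layer_labels)
    if len(layer_labels) != len(radii):
        raise InvalidGeometryError("need exactly one label per layer")
    for lab in layer_labels:
        if lab not in TISSUE_IDS:
            raise InvalidGeometryError(f"unknown tissue label {lab!r}")

    rng = np.random.default_rng(seed)
    points: List[np.ndarray] = []
    stations = _radial_stations(radii, resolution)
    station_radii = np.array([r for r, _ in stations])
    for k, (r, _is_interface) in enumerate(stations):
        # clamp tangential spacing to 2x the nearest radial gap so thin
        # layers are resolved (no tetrahedra tunneling through a shell)
        gaps = np.abs(station_radii - r)
        gaps = gaps[gaps > 1e-12]
        gap = min(gaps.min() if gaps.size else r, r)
        spacing = min(resolution, 2.0 * gap)
        n = _shell_point_count(r, spacing)
        phase = float(rng.uniform(0.0, 2.0 * np.pi))
        points.append(fibonacci_sphere(n, r, phase=phase))
    points.append(np.zeros((1, 3)))

    # conforming shells on tumor-part interfaces
    if refine_spheres:
        local_res = {}
        for center, r in refine_spheres:
            c = np.asarray(center, dtype=float)
            # fine enough that the polyhedral ball volume error stays ~2-3%
            lr = min(resolution, max(r / 3.0, 0.75))
            local_res[tuple(center)] = lr
            n = _shell_point_count(r, lr)
            phase = float(rng.uniform(0.0, 2.0 * np.pi))
            shell = fibonacci_sphere(n, r, phase=phase) + c
            points.append(shell)
            points.append(c[None, :])
        pts = np.concatenate(points)
        # drop background points in a band around each refinement shell so
        # no sliver forms between the background lattice and the shell
        keep = np.ones(len(pts), dtype=bool)
        n_background = sum(len(p) for p in points[: -2 * len(refine_spheres)])
        for center, r in refine_spheres:
            c = np.asarray(center, dtype=float)
            band = 0.45 * max(local_res[tuple(center)], resolution / 2.0)
            d = np.linalg.norm(pts[:n_background] - c, axis=1)
            keep[:n_background] &= np.abs(d - r) > band
        pts = pts[keep]
    else:
        pts = np.concatenate(points)

    # deduplicate coincident points (e.g. tumor center on the head center)
    _, uniq = np.unique(np.round(pts / 1e-6).astype(np.int64), axis=0, return_index=True)
    pts = pts[np.sort(uniq)]

    tri = Delaunay(pts)
    elements = tri.simplices.astype(np.int64)
    nodes = pts

    # orient positively and drop degenerate slivers (boundary round-off)
    p = nodes[elements]
    det = np.linalg.det(p[:, 1:] - p[:, :1])
    neg = det < 0
    elements[neg] = elements[neg][:, [0, 1, 3, 2]]
    vol = np.abs(det) / 6.0
    good = vol > 1e-9 * resolution**3
    elements = elements[good]

    # label by centroid radius
    centroids = nodes[elements].mean(axis=1)
    rc = np.linalg.norm(centroids, axis=1)
    labels = np.empty(len(elements), dtype=np.int32)
    bounds = radii + [0.0]
    for k, lab in enumerate(layer_labels):
        mask = (rc <= bounds[k] + 1e-9) & (rc > bounds[k + 1] - 1e-9)
        labels[mask] = TISSUE_IDS[lab]
        if not mask.any():
            raise MeshingError(
                f"resolution {resolution} mm too coarse to resolve layer "
                f"{lab!r} ({bounds[k]}-{bounds[k+1]} mm)"
            )
    # anything numerically outside the outermost bound joins the outer layer
    outside = rc > bounds[0] + 1e-9
    labels[outside] = TISSUE_IDS[layer_labels[0]]

    return HeadMesh(
        nodes=nodes,
        elements=elements,
        labels=labels,
        layer_radii=tuple(radii),
        layer_labels=layer_labels,
    )


# ---------------------------------------------------------------------------
# tumor embedding
# ---------------------------------------------------------------------------

def embed_tumor(mesh: HeadMesh, spec: TumorSpec) -> HeadMesh:
    """Relabel elements whose centroid lies inside the tumor parts.

    Innermost part wins (resection inside core inside shell). The tumor
    must displace brain tissue only; elements of any other tissue inside
    the tumor ball raise :class:`InvalidGeometryError` listing offenders.
    """
    center = np.asarray(spec.center, dtype=float)
    out = mesh.copy()
    centroids = out.element_centroids()
    d = np.linalg.norm(centroids - center, axis=1)

    inside_shell = d <= spec.shell_radius
    if not inside_shell.any():
        raise InvalidGeometryError(
            "tumor specification selects no elements (centered outside the mesh?)"
        )
    brain_ids = {TISSUE_IDS[l] for l in BRAIN_LABELS} | {
        TISSUE_IDS[l] for l in ("tumor_shell", "tumor_core", "resection")
    }
    offending = np.flatnonzero(
        inside_shell & ~np.isin(out.labels, list(brain_ids))
    )
    if offending.size:
        names = sorted({ID_TO_TISSUE[int(l)] for l in out.labels[offending]})
        raise InvalidGeometryError(
            f"tumor intersects non-brain tissue {names}; offending elements "
            f"{offending[:20].tolist()}{'...' if offending.size > 20 else ''}"
        )

    # outermost to innermost so inner labels overwrite
    for label, radius in reversed(spec.nested_parts):
        out.labels[d <= radius] = TISSUE_IDS[label]
    out._volumes = None
    out._boundary = mesh._boundary  # geometry unchanged
    return out


# ---------------------------------------------------------------------------
# conductivity assignment
# ---------------------------------------------------------------------------

def assign_conductivity(
    mesh: HeadMesh,
    table: Optional[TissueConductivityTable] = None,
    wm_anisotropy_ratio: Optional[float] = None,
) -> HeadMesh:
    """Attach per-element 3x3 conductivity tensors (S/m).

    Isotropic sigma*I by default. With ``wm_anisotropy_ratio`` = sigma_radial
    / sigma_tangential, white-matter tensors become radially anisotropic
    (radial direction from the head center through the element centroid) with
    the geometric mean of the eigenvalues preserved at the isotropic WM value.
    """
    if table is None:
        table = TissueConductivityTable.default()
    out = mesh.copy()
    labels_present = out.label_names()
    table.require(labels_present)

    m = len(out.elements)
    sigma = np.empty(m)
    for lab in labels_present:
        sigma[out.labels == TISSUE_IDS[lab]] = table[lab]
    tensors = sigma[:, None, None] * np.eye(3)[None, :, :]

    if wm_anisotropy_ratio is not None:
        ratio = float(wm_anisotropy_ratio)
        if ratio <= 0:
            raise ValueError("anisotropy ratio must be positive")
        wm = out.labels == TISSUE_IDS["wm"]
        if wm.any() and ratio != 1.0:
            c = out.element_centroids()[wm]
            r = np.linalg.norm(c, axis=1, keepdims=True)
            rhat = np.where(r > 1e-12, c / np.maximum(r, 1e-12), [[0, 0, 1.0]])
            s = table["wm"]
            s_rad = s * ratio ** (2.0 / 3.0)
            s_tan = s * ratio ** (-1.0 / 3.0)
            proj = np.einsum("ij,ik->ijk", rhat, rhat)
            tensors[wm] = s_tan * np.eye(3)[None] + (s_rad - s_tan) * proj
    out.conductivity = tensors
    return out


# ---------------------------------------------------------------------------
# intracranial reduction
# ---------------------------------------------------------------------------

def strip_to_intracranial(mesh: HeadMesh) -> HeadMesh:
    """Remove all compartments outside the CSF; the CSF surface becomes the
    active outer boundary. Idempotent."""
    keep_ids = [TISSUE_IDS[l] for l in INTRACRANIAL_LABELS]
    if TISSUE_IDS["csf"] not in mesh.labels:
        raise InvalidGeometryError("mesh has no CSF compartment to strip to")
    mask = np.isin(mesh.labels, keep_ids)
    if mask.all():
        return mesh.copy()
    elements = mesh.elements[mask]
    labels = mesh.labels[mask]
    used = np.unique(elements)
    remap = -np.ones(len(mesh.nodes), dtype=np.int64)
    remap[used] = np.arange(len(used))
    new_layers = [
        (r, lab)
        for r, lab in zip(mesh.layer_radii, mesh.layer_labels)
        if lab in INTRACRANIAL_LABELS
    ]
    return HeadMesh(
        nodes=mesh.nodes[used],
        elements=remap[elements],
        labels=labels.copy(),
        conductivity=None if mesh.conductivity is None else mesh.conductivity[mask],
        layer_radii=tuple(r for r, _ in new_layers),
        layer_labels=tuple(lab for _, lab in new_layers),
    )
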