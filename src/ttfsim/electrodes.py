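"""Electrode layouts and stimulation configurations.

Transcranial montages use 3x3 patches of 10-mm-radius disk electrodes
(center spacing 22 mm vertical, 33 mm horizontal) on the skin surface:
an anteroposterior patch pair swept around the vertical axis in 15-degree
steps (12 rotations) plus five montages recreated from earlier modeling
studies, 17 montages in total. The total patch current is split equally
over its nine electrodes.

The intracranial layout spreads 101 disk electrodes over the CSF surface —
61 on 10-10-style upper rings and 40 on two lower rings — avoiding the
interhemispheric midline band and the inferior (tentorial/brainstem) cap,
plus one inferior reference electrode used only to build the lead-field
basis. Positions are computed by angular ring subdivision on the sphere;
on a spherical surrogate surface they approximate, not reproduce, a
realistic-anatomy layout.

Head frame: +z superior, +y anterior, +x right.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .meshing import HeadMesh

#: Default disk electrode dimensions (mm).
ELECTRODE_RADIUS_MM = 10.0
ELECTRODE_HEIGHT_MM = 2.5
SUBARRAY_RADIUS_MM = 3.0

#: Patch grid center-to-center spacings (mm).
PATCH_VERTICAL_SPACING_MM = 22.0
PATCH_HORIZONTAL_SPACING_MM = 33.0

#: Half-width of the interhemispheric exclusion band (mm) on the superior surface.
MIDLINE_EXCLUSION_MM = 8.0
#: Colatitude (deg) below which only the reference electrode may sit.
INFERIOR_EXCLUSION_DEG = 135.0


class LayoutError(ValueError):
    """Raised when an electrode layout violates surface or zone constraints."""


@dataclass(frozen=True)
class Electrode:
    """A disk electrode on the model's active outer surface."""

    id: int
    center: Tuple[float, float, float]
    radius: float = ELECTRODE_RADIUS_MM
    height: float = ELECTRODE_HEIGHT_MM
    role: str = "stimulation"  # or "reference"

    def position(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)


@dataclass(frozen=True)
class ElectrodeConfiguration:
    """A stimulation pattern: electrodes with signed current shares.

    ``currents`` are fractions of the total injected current I; they sum to
    zero exactly (+1 split over the source set, -1 over the sink set).
    """

    electrodes: Tuple[Electrode, ...]
    currents: Tuple[float, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.electrodes) != len(self.currents):
            raise ValueError("one current share per electrode required")
        total = math.fsum(self.currents)
        if abs(total) > 1e-12:
            raise ValueError(f"signed current shares must sum to 0, got {total}")

    @property
    def n_electrodes(self) -> int:
        return len(self.electrodes)

    def sources(self) -> List[Electrode]:
        return [e for e, c in zip(self.electrodes, self.currents) if c > 0]

    def sinks(self) -> List[Electrode]:
        return [e for e, c in zip(self.electrodes, self.currents) if c < 0]


def _orthonormal_tangents(direction: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Horizontal and vertical unit tangents at a point on the sphere.

    The vertical tangent points toward +z (superior) along the surface; the
    horizontal one is azimuthal. Falls back to x/y at the poles.
    """
    n = direction / np.linalg.norm(direction)
    zhat = np.array([0.0, 0.0, 1.0])
    if abs(n @ zhat) > 0.999:
        return np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])
    u = np.cross(zhat, n)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def make_patch(
    surface_radius: float,
    center_direction: Sequence[float],
    start_id: int = 0,
    radius: float = ELECTRODE_RADIUS_MM,
    role: str = "stimulation",
) -> List[Electrode]:
    """3x3 electrode grid centered on ``center_direction``, mapped onto the
    sphere of ``surface_radius`` with the exponential map (grid offsets are
    arc lengths along the surface, so spacings are preserved to first
    order)."""
    n = np.asarray(center_direction, dtype=float)
    n /= np.linalg.norm(n)
    u, v = _orthonormal_tangents(n)
    electrodes = []
    k = start_id
    for dv in (-PATCH_VERTICAL_SPACING_MM, 0.0, PATCH_VERTICAL_SPACING_MM):
        for du in (-PATCH_HORIZONTAL_SPACING_MM, 0.0, PATCH_HORIZONTAL_SPACING_MM):
            offset = du * u + dv * v
            t = np.linalg.norm(offset) / surface_radius  # arc angle
            if t > 0:
                d = offset / np.linalg.norm(offset)
                p = surface_radius * (math.cos(t) * n + math.sin(t) * d)
            else:
                p = surface_radius * n
            electrodes.append(
                Electrode(id=k, center=tuple(p), radius=radius, role=role)
            )
            k += 1
    return electrodes


def _patch_pair_config(
    surface_radius: float,
    dir_source: np.ndarray,
    dir_sink: np.ndarray,
    name: str,
) -> ElectrodeConfiguration:
    src = make_patch(surface_radius, dir_source, start_id=0)
    snk = make_patch(surface_radius, dir_sink, start_id=9)
    currents = [1.0 / 9.0] * 9 + [-1.0 / 9.0] * 9
    return ElectrodeConfiguration(
        electrodes=tuple(src + snk), currents=tuple(currents), name=name
    )


def _direction(colat_deg: float, azim_deg: float) -> np.ndarray:
    """Unit vector at colatitude from +z and azimuth from +y (anterior),
    increasing toward +x (the subject's right)."""
    th = math.radians(colat_deg)
    ph = math.radians(azim_deg)
    return np.array(
        [math.sin(th) * math.sin(ph), math.sin(th) * math.cos(ph), math.cos(th)]
    )


def make_transcranial_rotations(mesh: HeadMesh) -> List[ElectrodeConfiguration]:
    """The anteroposterior patch pair rotated about the vertical axis in
    15-degree steps: 12 configurations (k = 0..11)."""
    R = mesh.outer_radius()
    configs = []
    for k in range(12):
        ang = 15.0 * k
        d_ant = _direction(90.0, ang)  # anterior at 0 degrees
        d_post = _direction(90.0, ang + 180.0)
        configs.append(
            _patch_pair_config(R, d_ant, d_post, name=f"rotation_{int(ang):03d}deg")
        )
    return configs


#: Approximate sphere-frame placements of the five montages recreated from
#: earlier modeling studies: (name, source (colat, azim), sink (colat, azim)).
LITERATURE_MONTAGES: Tuple[Tuple[str, Tuple[float, float], Tuple[float, float]], ...] = (
    ("anteroposterior_low_posterior", (90.0, 0.0), (115.0, 180.0)),
    ("top_back", (25.0, 0.0), (90.0, 180.0)),
    ("above_ears", (65.0, 90.0), (65.0, 270.0)),
    ("top_neck", (15.0, 0.0), (140.0, 180.0)),
    ("behind_ears", (90.0, 135.0), (90.0, 225.0)),
)


def make_literature_configs(mesh: HeadMesh) -> List[ElectrodeConfiguration]:
    """The five patch-pair montages recreated from prior modeling studies."""
    R = mesh.outer_radius()
    configs = []
    for name, (c1, a1), (c2, a2) in LITERATURE_MONTAGES:
        configs.append(
            _patch_pair_config(R, _direction(c1, a1), _direction(c2, a2), name=name)
        )
    return configs


def make_transcranial_set(mesh: HeadMesh) -> List[ElectrodeConfiguration]:
    """Complete transcranial montage set: 12 rotations + 5 literature = 17."""
    return make_transcranial_rotations(mesh) + make_literature_configs(mesh)


# ---------------------------------------------------------------------------
# intracranial layout
# ---------------------------------------------------------------------------

#: (colatitude deg, electrode count, azimuthal offset deg) for the upper
#: 10-10-style rings (61 electrodes) and the two added lower rings (40).
UPPER_RINGS: Tuple[Tuple[float, int, float], ...] = (
    (18.0, 4, 45.0),
    (36.0, 8, 22.5),
    (54.0, 12, 15.0),
    (72.0, 16, 11.25),
    (90.0, 21, 0.0),
)
LOWER_RINGS: Tuple[Tuple[float, int, float], ...] = (
    (105.0, 20, 9.0),
    (120.0, 20, 0.0),
)

#: Reference electrode direction: inferior, posterior (brainstem region).
REFERENCE_DIRECTION = (168.0, 180.0)


def _in_excluded_zone(p: np.ndarray) -> bool:
    """Interhemispheric midline band (superior) or the inferior cap."""
    if p[2] > 1e-6 and abs(p[0]) < MIDLINE_EXCLUSION_MM:
        return True
    r = np.linalg.norm(p)
    colat = math.degrees(math.acos(np.clip(p[2] / r, -1, 1)))
    return colat > INFERIOR_EXCLUSION_DEG


def place_intracranial_electrodes(
    mesh: HeadMesh, radius: float = ELECTRODE_RADIUS_MM
) -> List[Electrode]:
    """101 stimulation electrodes on the CSF surface plus one reference.

    Upper rings follow a 10-10-style angular subdivision (61 electrodes);
    two additional rings below add 40. No electrode sits in the
    interhemispheric midline band or the inferior exclusion cap; the
    reference sits inferiorly on the brainstem region and is excluded from
    stimulation pairs.
    """
    R = mesh.outer_radius()
    electrodes: List[Electrode] = []
    k = 0
    for colat, count, offset in UPPER_RINGS + LOWER_RINGS:
        for j in range(count):
            azim = offset + 360.0 * j / count
            p = R * _direction(colat, azim)
            if _in_excluded_zone(p):
                raise LayoutError(
                    f"electrode {k} (colat {colat}, azim {azim:.1f}) falls in an "
                    "excluded zone"
                )
            electrodes.append(
                Electrode(id=k, center=tuple(p), radius=radius, role="stimulation")
            )
            k += 1
    ref = Electrode(
        id=k,
        center=tuple(R * _direction(*REFERENCE_DIRECTION)),
        radius=radius,
        role="reference",
    )
    electrodes.append(ref)
    return electrodes


def enumerate_pairs(
    electrodes: Sequence[Electrode],
) -> List[ElectrodeConfiguration]:
    """All unordered stimulation-electrode pairs as unit-current source/sink
    configurations, ordered lexicographically by ascending ids."""
    stim = sorted(
        (e for e in electrodes if e.role == "stimulation"), key=lambda e: e.id
    )
    if len(stim) < 2:
        raise LayoutError("need at least 2 stimulation electrodes to form pairs")
    configs = []
    for a, b in itertools.combinations(stim, 2):
        configs.append(
            ElectrodeConfiguration(
                electrodes=(a, b), currents=(1.0, -1.0), name=f"pair_{a.id}_{b.id}"
            )
        )
    return configs


def expand_to_subarray(
    config: ElectrodeConfiguration,
    surface_radius: Optional[float] = None,
    sub_radius: float = SUBARRAY_RADIUS_MM,
    spacing: float = 8.0,
) -> ElectrodeConfiguration:
    """Replace each disk electrode by a 2x2 array of small electrodes
    sharing its current equally (total current per site unchanged)."""
    if spacing < 2 * sub_radius:
        raise LayoutError(
            f"sub-electrode spacing {spacing} mm overlaps disks of radius {sub_radius} mm"
        )
    new_elecs: List[Electrode] = []
    new_currents: List[float] = []
    k = 0
    for e, c in zip(config.electrodes, config.currents):
        p = e.position()
        R = surface_radius if surface_radius is not None else float(np.linalg.norm(p))
        n = p / np.linalg.norm(p)
        u, v = _orthonormal_tangents(n)
        for su in (-0.5, 0.5):
            for sv in (-0.5, 0.5):
                q = p + su * spacing * u + sv * spacing * v
                q *= R / np.linalg.norm(q)
                new_elecs.append(
                    Electrode(id=k, center=tuple(q), radius=sub_radius, role=e.role)
                )
                new_currents.append(c / 4.0)
                k += 1
    return ElectrodeConfiguration(
        electrodes=tuple(new_elecs),
        currents=tuple(new_currents),
        name=config.name + "_subarray",
    )
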