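"""Synthetic cortical geometry: meshes, source spaces, parcellations, patches.

The cortical model is a pair of radially perturbed icospheres standing in for
the two pial hemisphere surfaces.  Each mesh vertex is a candidate source
location; an angular band construction assigns the four sensorimotor labels
(precentral gyrus, central sulcus, postcentral gyrus, postcentral sulcus) in
anterior-to-posterior order, with everything else labelled ``other``.

Coordinates are surface RAS in millimetres: +x right, +y anterior, +z
superior, origin at the centre of the (spherical) head model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import trimesh

__all__ = [
    "TriangleMesh",
    "SourceSpace",
    "Parcellation",
    "CortexModel",
    "ROI_NAMES",
    "build_icosphere",
    "build_synthetic_cortex",
    "make_source_space",
    "combine_source_spaces",
    "synthetic_parcellation",
    "neighbors_within",
    "mesh_adjacency",
    "grow_patch",
    "build_cortex_model",
]

#: the four sensorimotor region names, anterior -> posterior
ROI_NAMES = (
    "precentral_gyrus",
    "central_sulcus",
    "postcentral_gyrus",
    "postcentral_sulcus",
)

OTHER_LABEL = 0


@dataclass
class TriangleMesh:
    """A triangulated hemisphere surface.

    Parameters
    ----------
    vertices : (n, 3) float array, mm, surface RAS
    faces : (m, 3) int array of vertex indices
    hemisphere : "left" or "right"
    center : (3,) array, centre of the underlying sphere (mm)
    nominal_radius : radius of the unperturbed sphere (mm)
    """

    vertices: np.ndarray
    faces: np.ndarray
    hemisphere: str = "left"
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    nominal_radius: float = 1.0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.center = np.asarray(self.center, dtype=float)
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be 'left' or 'right', got {self.hemisphere!r}")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def euler_characteristic(self) -> int:
        edges = set()
        for tri in self.faces:
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                edges.add((min(a, b), max(a, b)))
        return self.n_vertices - len(edges) + len(self.faces)


@dataclass
class SourceSpace:
    """Discrete source locations with fixed (surface-normal) orientations."""

    positions: np.ndarray  # (n, 3) mm
    orientations: np.ndarray  # (n, 3) unit vectors
    hemispheres: np.ndarray  # (n,) of "left"/"right"
    vertex_ids: np.ndarray  # (n,) vertex index within the hemisphere mesh

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        self.hemispheres = np.asarray(self.hemispheres)
        self.vertex_ids = np.asarray(self.vertex_ids, dtype=np.int64)

    @property
    def n_sources(self) -> int:
        return len(self.positions)

    def hemisphere_mask(self, hemisphere: str) -> np.ndarray:
        return self.hemispheres == hemisphere


@dataclass
class Parcellation:
    """Per-source anatomical labels (synthetic stand-in for a cortical atlas).

    ``labels[j]`` is an integer label id; ``label_table`` maps each id to a
    ``(name, hemisphere)`` pair.  Label 0 is ``other`` and is shared between
    hemispheres; the four sensorimotor labels exist once per hemisphere.
    """

    labels: np.ndarray
    label_table: Mapping[int, tuple[str, str]]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)

    def roi_label_ids(self, hemisphere: str | None = None) -> set[int]:
        """Ids of the four sensorimotor labels, optionally for one hemisphere."""
        out = set()
        for lid, (name, hemi) in self.label_table.items():
            if name in ROI_NAMES and (hemisphere is None or hemi == hemisphere):
                out.add(lid)
        return out

    def roi_mask(self, hemisphere: str | None = None) -> np.ndarray:
        ids = self.roi_label_ids(hemisphere)
        return np.isin(self.labels, sorted(ids))

    def name_of(self, label_id: int) -> str:
        return self.label_table[int(label_id)][0]


def build_icosphere(subdivisions: int, radius: float, hemisphere: str = "left") -> TriangleMesh:
    """Subdivided icosahedron with ``10 * 4**subdivisions + 2`` vertices.

    Vertices lie exactly at distance ``radius`` from the origin; faces form a
    closed, outward-oriented 2-manifold.
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be non-negative")
    if subdivisions > 7:
        raise ValueError("subdivisions > 7 refused (memory sanity)")
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    v = np.asarray(m.vertices, dtype=float)
    # snap exactly onto the sphere (trimesh is already close)
    v *= radius / np.linalg.norm(v, axis=1, keepdims=True)
    return TriangleMesh(v, np.asarray(m.faces), hemisphere, np.zeros(3), radius)


def _fold_displacement(unit: np.ndarray, amplitude: float, phases: np.ndarray) -> np.ndarray:
    """Smooth angular sinusoid in the spherical angles; |disp| <= amplitude."""
    theta = np.arccos(np.clip(unit[:, 2], -1.0, 1.0))  # polar angle from +z
    phi = np.arctan2(unit[:, 1], unit[:, 0])  # azimuth
    return amplitude * np.sin(4 * theta + phases[0]) * np.cos(3 * phi + phases[1])


def build_synthetic_cortex(
    subdivisions: int,
    fold_amplitude: float = 5.0,
    hemisphere_gap: float = 8.0,
    seed: int = 0,
    radius: float = 35.0,
) -> tuple[TriangleMesh, TriangleMesh]:
    """Two mirror-image folded icospheres separated along the x axis.

    The radial perturbation is a deterministic product of integer-harmonic
    sinusoids whose phases are drawn from ``seed``, giving smooth "gyri" and
    "sulci" with ``max |r - radius| <= fold_amplitude``.  Hemisphere centres
    sit at ``x = -/+ (radius + hemisphere_gap / 2)``.

    Returns ``(left, right)``.
    """
    if fold_amplitude >= radius / 4:
        raise ValueError("fold_amplitude must be < radius / 4")
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0, 2 * np.pi, size=2)
    base = build_icosphere(subdivisions, radius)
    unit = base.vertices / radius
    disp = _fold_displacement(unit, fold_amplitude, phases)
    local = unit * (radius + disp)[:, None]

    offset = radius + hemisphere_gap / 2.0
    right_center = np.array([offset, 0.0, 0.0])
    left_center = np.array([-offset, 0.0, 0.0])
    right = TriangleMesh(local + right_center, base.faces.copy(), "right", right_center, radius)
    # mirror through x=0; reverse face winding to keep normals outward
    left_v = local * np.array([-1.0, 1.0, 1.0]) + left_center
    left = TriangleMesh(left_v, base.faces[:, ::-1].copy(), "left", left_center, radius)
    return left, right


def make_source_space(mesh: TriangleMesh) -> SourceSpace:
    """One source per mesh vertex, oriented along the outward surface normal.

    Normals are area-weighted averages of adjacent face normals, normalised
    to unit length.  A zero-area face raises an error naming the face.
    """
    v, f = mesh.vertices, mesh.faces
    e1 = v[f[:, 1]] - v[f[:, 0]]
    e2 = v[f[:, 2]] - v[f[:, 0]]
    face_cross = np.cross(e1, e2)  # |cross| = 2 * area, direction = face normal
    areas = np.linalg.norm(face_cross, axis=1)
    bad = np.flatnonzero(areas < 1e-12)
    if bad.size:
        raise ValueError(f"degenerate (zero-area) faces: {bad.tolist()}")
    normals = np.zeros_like(v)
    for k in range(3):
        np.add.at(normals, f[:, k], face_cross)
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = normals / norms
    n = len(v)
    return SourceSpace(
        positions=v.copy(),
        orientations=normals,
        hemispheres=np.full(n, mesh.hemisphere, dtype=object),
        vertex_ids=np.arange(n),
    )


def combine_source_spaces(spaces: Sequence[SourceSpace]) -> SourceSpace:
    """Concatenate per-hemisphere source spaces; global index = offset + vertex id."""
    return SourceSpace(
        positions=np.vstack([s.positions for s in spaces]),
        orientations=np.vstack([s.orientations for s in spaces]),
        hemispheres=np.concatenate([s.hemispheres for s in spaces]),
        vertex_ids=np.concatenate([s.vertex_ids for s in spaces]),
    )


def _band_coordinate(source_space: SourceSpace, centers: Mapping[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Angular band coordinate psi and lateral coordinate m per source.

    psi = atan2(-y, z) in hemisphere-local coordinates: 0 at the vertex
    (top), negative anterior, positive posterior.  m is the cosine of the
    angle to the lateral pole (+x for the right hemisphere, -x for the left).
    """
    psi = np.empty(source_space.n_sources)
    m = np.empty(source_space.n_sources)
    for hemi, sign in (("left", -1.0), ("right", 1.0)):
        mask = source_space.hemisphere_mask(hemi)
        if not mask.any():
            continue
        local = source_space.positions[mask] - centers[hemi]
        u = local / np.linalg.norm(local, axis=1, keepdims=True)
        psi[mask] = np.arctan2(-u[:, 1], u[:, 2])
        m[mask] = sign * u[:, 0]
    return psi, m


def synthetic_parcellation(
    source_space: SourceSpace,
    hemisphere_centers: Mapping[str, np.ndarray],
    band_center: float = 0.0,
    band_width: float = 0.19,
    lateral_range: tuple[float, float] = (-0.75, 0.75),
) -> Parcellation:
    """Four contiguous angular bands per hemisphere plus ``other``.

    Bands run anterior to posterior in the angle ``psi = atan2(-y, z)``
    (hemisphere-local), each ``band_width`` radians wide and centred as a
    group on ``band_center``; the lateral extent is limited to sources whose
    lateral-pole cosine lies in ``lateral_range``.  With the defaults the four
    sensorimotor labels cover about 9 % of all sources, the chance level used
    by the random-patch null.
    """
    if band_width < 0:
        raise ValueError("band_width must be non-negative")
    lo, hi = lateral_range
    covered = (4 * band_width / (2 * np.pi)) * ((hi - lo) / 2.0)
    if covered > 0.5:
        raise ValueError("bands would cover more than 50% of the surface")
    psi, m = _band_coordinate(source_space, hemisphere_centers)
    labels = np.zeros(source_space.n_sources, dtype=np.int64)
    label_table: dict[int, tuple[str, str]] = {OTHER_LABEL: ("other", "both")}
    start = band_center - 2 * band_width
    next_id = 1
    for hemi in ("left", "right"):
        hmask = source_space.hemisphere_mask(hemi)
        for k, name in enumerate(ROI_NAMES):
            b_lo = start + k * band_width
            b_hi = b_lo + band_width
            sel = hmask & (psi >= b_lo) & (psi < b_hi) & (m >= lo) & (m <= hi)
            labels[sel] = next_id
            label_table[next_id] = (name, hemi)
            next_id += 1
    return Parcellation(labels, label_table)


def neighbors_within(source_space: SourceSpace, index: int, radius: float) -> np.ndarray:
    """Sorted indices of sources within Euclidean ``radius`` of ``index`` (inclusive)."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    if not 0 <= index < source_space.n_sources:
        raise IndexError(f"source index {index} out of range")
    d = np.linalg.norm(source_space.positions - source_space.positions[index], axis=1)
    return np.flatnonzero(d <= radius)


def mesh_adjacency(meshes: Iterable[TriangleMesh]) -> sp.csr_matrix:
    """Vertex adjacency over the concatenated meshes (hemispheres stay disjoint)."""
    rows, cols = [], []
    offset = 0
    for mesh in meshes:
        f = mesh.faces
        for a, b in ((0, 1), (1, 2), (2, 0)):
            rows.append(f[:, a] + offset)
            cols.append(f[:, b] + offset)
        offset += mesh.n_vertices
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    data = np.ones(len(r), dtype=np.int8)
    adj = sp.coo_matrix((data, (r, c)), shape=(offset, offset)).tocsr()
    adj = adj + adj.T
    adj.data[:] = 1
    return adj.tocsr()


def grow_patch(
    source_space: SourceSpace,
    topology: TriangleMesh | Sequence[TriangleMesh] | sp.spmatrix,
    seed_vertex: int,
    size: int,
) -> np.ndarray:
    """Contiguous patch of exactly ``size`` sources grown from ``seed_vertex``.

    Growth is breadth-first over mesh edges, ring by ring; when a ring does
    not fit entirely, its members are admitted in order of ascending
    Euclidean distance to the seed, then ascending index.  Deterministic.
    """
    n = source_space.n_sources
    if not 1 <= size <= n:
        raise ValueError(f"size must be in [1, {n}]")
    if not 0 <= seed_vertex < n:
        raise IndexError("seed_vertex out of range")
    if sp.issparse(topology):
        adj = topology.tocsr()
    elif isinstance(topology, TriangleMesh):
        adj = mesh_adjacency([topology])
    else:
        adj = mesh_adjacency(list(topology))
    if adj.shape[0] != n:
        raise ValueError("adjacency size does not match source space")

    seed_pos = source_space.positions[seed_vertex]
    in_patch = np.zeros(n, dtype=bool)
    members: list[int] = [seed_vertex]
    in_patch[seed_vertex] = True
    frontier = np.array([seed_vertex])
    while len(members) < size:
        ring = np.unique(adj[frontier].indices)
        ring = ring[~in_patch[ring]]
        if ring.size == 0:
            raise ValueError(
                f"connected component of seed {seed_vertex} smaller than requested size {size}"
            )
        need = size - len(members)
        if ring.size > need:
            d = np.linalg.norm(source_space.positions[ring] - seed_pos, axis=1)
            order = np.lexsort((ring, d))
            ring = ring[order[:need]]
        in_patch[ring] = True
        members.extend(ring.tolist())
        frontier = ring
    return np.array(sorted(members), dtype=np.int64)


@dataclass
class CortexModel:
    """Bundle of the two hemisphere meshes with derived structures.

    This is the geometric workbench every later stage consumes: the combined
    source space (left hemisphere first), the synthetic parcellation and the
    vertex adjacency used for patch growth.
    """

    left: TriangleMesh
    right: TriangleMesh
    source_space: SourceSpace
    parcellation: Parcellation
    adjacency: sp.csr_matrix

    @property
    def hemisphere_centers(self) -> dict[str, np.ndarray]:
        return {"left": self.left.center, "right": self.right.center}

    def hemisphere_of(self, index: int) -> str:
        return str(self.source_space.hemispheres[index])


def build_cortex_model(
    subdivisions: int = 4,
    fold_amplitude: float = 5.0,
    hemisphere_gap: float = 8.0,
    radius: float = 35.0,
    band_center: float = 0.0,
    band_width: float = 0.19,
    lateral_range: tuple[float, float] = (-0.75, 0.75),
    seed: int = 0,
) -> CortexModel:
    """Construct the full synthetic cortical model (meshes, sources, labels)."""
    left, right = build_synthetic_cortex(
        subdivisions, fold_amplitude, hemisphere_gap, seed=seed, radius=radius
    )
    ss = combine_source_spaces([make_source_space(left), make_source_space(right)])
    parc = synthetic_parcellation(
        ss,
        {"left": left.center, "right": right.center},
        band_center=band_center,
        band_width=band_width,
        lateral_range=lateral_range,
    )
    adj = mesh_adjacency([left, right])
    return CortexModel(left, right, ss, parc, adj)
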