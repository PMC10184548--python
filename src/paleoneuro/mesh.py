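"""Triangle-mesh volumetrics and linear measurements for digital endocasts.

Cranial endocasts and endosseous labyrinths arrive as surface meshes
segmented from CT volumes (STL/OBJ/PLY, coordinates in millimetres).  This
module replaces interactive mesh-software measurement with auditable
computation: enclosed volume via the signed-tetrahedron (divergence) sum,
straight-line distances, and polyline (curved) lengths.

Volumes are reported in cm**3 -- the unit conventional for endocranial
volume -- with the mm**3 -> cm**3 conversion applied exactly once, at
output.  The exclusion of neurovascular features from an endocast volume is
a segmentation-time decision made by whoever produced the mesh; this module
measures the surface it is given.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TriangleMesh",
    "Polyline",
    "MeshError",
    "OpenMeshWarning",
    "load_mesh",
    "save_stl",
    "mesh_volume",
    "linear_distance",
    "polyline_length",
]

MM3_PER_CM3 = 1000.0

#: Coordinates closer than this (mm) are treated as the same vertex when
#: welding per-facet STL vertices into a shared-vertex mesh.
WELD_TOLERANCE_MM = 1e-6


class MeshError(ValueError):
    """A mesh violates a precondition (open, non-manifold, unorientable)."""


class OpenMeshWarning(UserWarning):
    """Volume was computed on a mesh with boundary edges (permissive mode)."""


@dataclass
class TriangleMesh:
    """An oriented triangle surface in millimetres.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in mm; must be finite.
    faces : (m, 3) int array
        Vertex-index triples.  For volume computation the surface must be
        closed (every edge shared by exactly two faces) and consistently
        oriented with outward-facing normals.
    name : str
        Free-text label carried through to reports.
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be an (m, 3) array")
        if not np.isfinite(self.vertices).all():
            raise MeshError("vertex coordinates must be finite")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise MeshError("face indices reference missing vertices")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)


@dataclass
class Polyline:
    """An ordered sequence of >= 2 finite 3D points (mm), e.g. a duct centreline."""

    points: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("polyline points must be an (n, 3) array")
        if len(self.points) < 2:
            raise ValueError("a polyline needs at least 2 points")
        if not np.isfinite(self.points).all():
            raise ValueError("polyline coordinates must be finite")


def _weld(vertices: np.ndarray, faces: np.ndarray, tol: float = WELD_TOLERANCE_MM):
    """Merge vertices closer than ``tol`` (deterministic grid snap).

    STL stores three independent vertices per facet; welding restores the
    shared-vertex topology that edge-manifold checks require.
    """
    keys = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    return vertices[first], inverse[faces]


def _directed_edges(faces: np.ndarray) -> np.ndarray:
    """All 3m directed edges (a, b) in traversal order."""
    return np.concatenate(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]], axis=0
    )


def _edge_topology(faces: np.ndarray):
    """Return (boundary_edge_count, undirected edge -> face list, manifold ok)."""
    edges = _directed_edges(faces)
    und = np.sort(edges, axis=1)
    _, inverse, counts = np.unique(
        und, axis=0, return_inverse=True, return_counts=True
    )
    boundary = int((counts == 1).sum())
    nonmanifold = int((counts > 2).sum())
    return boundary, nonmanifold, inverse


def _face_adjacency(faces: np.ndarray, edge_ids: np.ndarray):
    """Map each face to its neighbours across shared undirected edges."""
    m = len(faces)
    owners: dict[int, list[int]] = {}
    for k, eid in enumerate(edge_ids):
        owners.setdefault(int(eid), []).append(k % m)
    adj: list[list[int]] = [[] for _ in range(m)]
    for fs in owners.values():
        if len(fs) == 2 and fs[0] != fs[1]:
            adj[fs[0]].append(fs[1])
            adj[fs[1]].append(fs[0])
    return adj


def _orient_components(faces: np.ndarray, edge_ids: np.ndarray):
    """Propagate a consistent winding across each connected component.

    Starting from the lowest-index unvisited face, neighbours sharing an
    edge are flipped whenever they traverse that edge in the same direction
    (consistent winding traverses a shared edge in opposite directions).
    Returns the reoriented faces and per-face component labels.  Raises
    MeshError if propagation reaches a contradiction (unorientable surface,
    e.g. a Mobius-like configuration).
    """
    m = len(faces)
    faces = faces.copy()
    adj = _face_adjacency(faces, edge_ids)

    def edge_set(f):
        a, b, c = faces[f]
        return {(a, b), (b, c), (c, a)}

    component = np.full(m, -1, dtype=int)
    label = 0
    for seed in range(m):
        if component[seed] != -1:
            continue
        component[seed] = label
        queue = deque([seed])
        while queue:
            f = queue.popleft()
            f_edges = edge_set(f)
            for g in adj[f]:
                g_edges = edge_set(g)
                same = f_edges & g_edges
                opposite = f_edges & {(b, a) for a, b in g_edges}
                if component[g] == -1:
                    if same:
                        faces[g] = faces[g][::-1]
                    component[g] = label
                    queue.append(g)
                else:
                    # already oriented: consistent neighbours must share the
                    # edge in opposite directions
                    if same and not opposite:
                        raise MeshError(
                            "mesh is not orientable: winding contradiction "
                            "during orientation propagation"
                        )
        label += 1
    return faces, component


def _signed_volume_mm3(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Per-face signed tetrahedron volumes det(v0, v1, v2) / 6 in mm**3."""
    v0 = vertices[faces[:, 0]]
    v1 = vertices[faces[:, 1]]
    v2 = vertices[faces[:, 2]]
    return np.einsum("ij,ij->i", v0, np.cross(v1, v2)) / 6.0


def mesh_volume(mesh: TriangleMesh, *, permissive: bool = False) -> float:
    """Enclosed volume of a closed triangle mesh, in cm**3.

    The volume is the absolute signed-tetrahedron sum per connected
    component (so the result is invariant under a globally reversed
    winding and additive over disjoint closed shells), converted from
    mm**3 once at the end.

    Parameters
    ----------
    mesh : TriangleMesh
    permissive : bool
        If True, a mesh with boundary edges (holes) is integrated anyway
        and an :class:`OpenMeshWarning` is emitted instead of raising.
        Real fossil segmentations often carry small holes; the returned
        value is then only an approximation.

    Raises
    ------
    MeshError
        If the mesh has boundary edges (strict mode), non-manifold edges,
        or cannot be consistently oriented.
    """
    if mesh.n_faces == 0:
        raise MeshError("mesh has no faces")
    verts, faces = _weld(mesh.vertices, mesh.faces)
    boundary, nonmanifold, edge_ids = _edge_topology(faces)
    if nonmanifold:
        raise MeshError(
            f"mesh is non-manifold: {nonmanifold} edges shared by >2 faces"
        )
    if boundary:
        if not permissive:
            raise MeshError(
                f"open mesh: {boundary} boundary edges; volume of a "
                "non-closed surface is undefined (pass permissive=True "
                "to integrate anyway)"
            )
        warnings.warn(
            f"integrating an open mesh with {boundary} boundary edges; "
            "the volume is approximate",
            OpenMeshWarning,
            stacklevel=2,
        )
    faces, component = _orient_components(faces, edge_ids)
    signed = _signed_volume_mm3(verts, faces)
    total = 0.0
    for label in np.unique(component):
        total += abs(float(signed[component == label].sum()))
    return total / MM3_PER_CM3


def linear_distance(p, q) -> float:
    """Euclidean distance between two 3D points, in mm (digital calliper)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != (3,) or q.shape != (3,):
        raise ValueError("points must be 3-vectors")
    if not (np.isfinite(p).all() and np.isfinite(q).all()):
        raise ValueError("points must be finite")
    return float(np.linalg.norm(p - q))


def polyline_length(line: Polyline | np.ndarray) -> float:
    """Total length of a polyline in mm (sum of segment lengths).

    Always >= the straight-line distance between the endpoints.
    """
    if not isinstance(line, Polyline):
        line = Polyline(np.asarray(line))
    deltas = np.diff(line.points, axis=0)
    return float(np.linalg.norm(deltas, axis=1).sum())


def load_mesh(path, name: str | None = None) -> TriangleMesh:
    """Read an STL (binary or ASCII), OBJ or PLY surface into a TriangleMesh.

    Parsing is delegated to :mod:`trimesh`; vertices closer than the weld
    tolerance are merged so edge-manifold checks see shared topology.
    """
    import trimesh

    loaded = trimesh.load(str(path), force="mesh", process=False)
    verts = np.asarray(loaded.vertices, dtype=float)
    faces = np.asarray(loaded.faces, dtype=np.int64)
    verts, faces = _weld(verts, faces)
    return TriangleMesh(verts, faces, name=name or str(path))


def save_stl(mesh: TriangleMesh, path) -> None:
    """Write a binary STL (used for synthetic fixtures and round-trips)."""
    import trimesh

    tm = trimesh.Trimesh(
        vertices=mesh.vertices, faces=mesh.faces, process=False
    )
    tm.export(str(path), file_type="stl")
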