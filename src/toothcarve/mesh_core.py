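"""Triangle-mesh container, standard-format I/O, and neighborhood queries.

The mesh model used throughout the package is an oriented 2-manifold
triangular mesh: every edge borders one or two triangles, and the two
triangles sharing an edge traverse it in opposite directions.  Dental
casts digitized by optical scanners arrive in this form (watertight,
mm-scale), typically as STL; holes appear only after feature regions
are deliberately removed.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import trimesh


class NonManifoldError(ValueError):
    """Raised when an input mesh violates the 2-manifold contract.

    Carries the offending edges in :attr:`edges` as (i, j) vertex-index
    pairs.
    """

    def __init__(self, message: str, edges=()):
        super().__init__(message)
        self.edges = list(edges)


@dataclass
class Neighborhood:
    """The n-ring vertex neighborhood of a center vertex.

    The 1-ring contains the center itself plus every vertex joined to it
    by an edge; the n-ring is the recursive 1-ring expansion of the
    (n-1)-ring.  Rings are therefore nested: ring n contains ring n-1.
    """

    center: int
    ring_order: int
    members: frozenset

    def __contains__(self, i):
        return i in self.members

    def __len__(self):
        return len(self.members)


@dataclass
class BoundaryLoop:
    """An ordered cyclic chain of boundary vertices.

    Each consecutive pair shares a boundary edge (an edge with exactly
    one incident triangle).  The loop is oriented so that the single
    incident triangle lies to the left of each directed edge, which
    fixes a deterministic normal convention for hole triangulation.
    """

    vertices: list

    def __len__(self):
        return len(self.vertices)

    def positions(self, mesh):
        return mesh.vertices[self.vertices]


class Mesh:
    """Indexed triangle mesh with adjacency caches.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex positions in model units (mm for dental data).
    faces : (m, 3) int array
        Ordered vertex-index triples with consistent winding.
    validate : bool
        Check the 2-manifold and consistent-winding invariants.
    """

    def __init__(self, vertices, faces, validate=True):
        self.vertices = np.ascontiguousarray(vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")
        self._build_adjacency()
        if validate:
            self._validate()

    # -- construction ------------------------------------------------

    def _build_adjacency(self):
        n = len(self.vertices)
        self._neighbors = [set() for _ in range(n)]
        self._vertex_faces = [[] for _ in range(n)]
        self._edge_faces = defaultdict(list)
        for fi, (a, b, c) in enumerate(self.faces):
            for u, v in ((a, b), (b, c), (c, a)):
                self._neighbors[u].add(int(v))
                self._neighbors[v].add(int(u))
                self._edge_faces[(min(u, v), max(u, v))].append(fi)
            self._vertex_faces[a].append(fi)
            self._vertex_faces[b].append(fi)
            self._vertex_faces[c].append(fi)

    def _validate(self):
        bad = [e for e, fs in self._edge_faces.items() if len(fs) > 2]
        if bad:
            raise NonManifoldError(
                f"{len(bad)} edge(s) shared by more than two triangles, "
                f"e.g. {bad[:5]}",
                edges=bad,
            )
        seen = set()
        dup = []
        for f in self.faces:
            key = tuple(sorted(f))
            if key in seen:
                dup.append(key)
            seen.add(key)
        if dup:
            raise NonManifoldError(
                f"{len(dup)} duplicate triangle(s), e.g. {dup[:5]}", edges=[]
            )
        # consistent winding: a shared edge must be traversed once in each
        # direction by its two triangles
        directed = defaultdict(int)
        for a, b, c in self.faces:
            for u, v in ((a, b), (b, c), (c, a)):
                directed[(u, v)] += 1
        bad = []
        for (u, v), fs in self._edge_faces.items():
            if len(fs) == 2 and (directed[(u, v)] != 1 or directed[(v, u)] != 1):
                bad.append((u, v))
        if bad:
            raise NonManifoldError(
                f"inconsistent winding across {len(bad)} edge(s), "
                f"e.g. {bad[:5]}",
                edges=bad,
            )

    # -- basic queries -----------------------------------------------

    def __repr__(self):
        return f"Mesh({len(self.vertices)} vertices, {len(self.faces)} faces)"

    @property
    def n_vertices(self):
        return len(self.vertices)

    @property
    def n_faces(self):
        return len(self.faces)

    @property
    def edges(self):
        return list(self._edge_faces)

    def vertex_neighbors(self, i):
        """Vertices joined to ``i`` by an edge (center excluded)."""
        return self._neighbors[i]

    def vertex_faces(self, i):
        """Indices of the 1-ring triangles sharing vertex ``i``."""
        return self._vertex_faces[i]

    def edge_face_indices(self, i, j):
        return self._edge_faces.get((min(i, j), max(i, j)), [])

    def is_boundary_edge(self, i, j):
        return len(self.edge_face_indices(i, j)) == 1

    def is_boundary_vertex(self, i):
        return any(
            self.is_boundary_edge(i, j) for j in self._neighbors[i]
        )

    def face_normals(self):
        v = self.vertices
        f = self.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        lens = np.linalg.norm(n, axis=1)
        lens[lens == 0] = 1.0
        return n / lens[:, None]

    def face_areas(self):
        v = self.vertices
        f = self.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(n, axis=1)

    def mean_edge_length(self):
        e = np.array(self.edges)
        d = self.vertices[e[:, 0]] - self.vertices[e[:, 1]]
        return float(np.linalg.norm(d, axis=1).mean())

    def bbox_diagonal(self):
        return float(
            np.linalg.norm(self.vertices.max(axis=0) - self.vertices.min(axis=0))
        )

    def euler_characteristic(self):
        return self.n_vertices - len(self._edge_faces) + self.n_faces

    def is_watertight(self):
        return all(len(fs) == 2 for fs in self._edge_faces.values())

    def copy(self):
        return Mesh(self.vertices.copy(), self.faces.copy(), validate=False)

    def canonical_hash(self):
        """Geometry hash invariant to vertex/face ordering.

        Sorts vertex rows (rounded) and re-expresses faces on the sorted
        order, so two loads of the same shape compare equal even if the
        reader permuted indices.
        """
        v = np.round(self.vertices, 9)
        order = np.lexsort((v[:, 2], v[:, 1], v[:, 0]))
        rank = np.empty(len(order), dtype=np.int64)
        rank[order] = np.arange(len(order))
        faces = np.sort(rank[self.faces], axis=1)
        faces = faces[np.lexsort((faces[:, 2], faces[:, 1], faces[:, 0]))]
        return hash((v[order].tobytes(), faces.tobytes()))

    def ordered_ring(self, i):
        """1-ring neighbors of ``i`` in counter-clockwise cyclic order.

        Counter-clockwise is defined by the face winding: in a face
        (i, a, b) the neighbor ``a`` precedes ``b`` around ``i``.  For a
        boundary vertex the result is the open fan path ordered the same
        way; for an interior vertex it is cyclic.
        """
        succ = {}
        for fi in self._vertex_faces[i]:
            f = self.faces[fi]
            k = int(np.where(f == i)[0][0])
            a, b = int(f[(k + 1) % 3]), int(f[(k + 2) % 3])
            succ[a] = b
        if not succ:
            return []
        starts = set(succ) - set(succ.values())
        start = min(starts) if starts else min(succ)
        ring = [start]
        while ring[-1] in succ:
            nxt = succ[ring[-1]]
            if nxt == ring[0]:
                break
            ring.append(nxt)
        return ring


# -- operations -------------------------------------------------------


def neighborhood(mesh: Mesh, i: int, n: int = 1) -> Neighborhood:
    """The n-ring neighborhood of vertex ``i``.

    The 1-ring is ``{i} ∪ {j : edge (i, j) exists}``; ring n is the
    1-ring expansion of ring n-1, i.e. breadth-first search to graph
    depth n including the center.
    """
    if not 0 <= i < mesh.n_vertices:
        raise IndexError(f"vertex index {i} out of range")
    if n < 1:
        raise ValueError("ring order must be >= 1")
    members = {i}
    frontier = {i}
    for _ in range(n):
        nxt = set()
        for j in frontier:
            nxt |= mesh.vertex_neighbors(j)
        nxt -= members
        members |= nxt
        frontier = nxt
        if not frontier:
            break
    return Neighborhood(center=i, ring_order=n, members=frozenset(members))


def ring_triangles(mesh: Mesh, i: int):
    """NeiT¹(i): the 1-ring triangles incident to vertex ``i``."""
    return list(mesh.vertex_faces(i))


def boundary_loops(mesh: Mesh):
    """Extract all boundary loops as ordered cyclic vertex chains.

    Every edge with exactly one incident triangle appears in exactly one
    loop.  Each loop is oriented so the incident triangle lies to the
    left of each directed edge, i.e. directed boundary edges follow the
    winding of their unique triangle.
    """
    succ = {}
    for (u, v), fs in mesh._edge_faces.items():
        if len(fs) != 1:
            continue
        f = mesh.faces[fs[0]]
        # directed as it appears in the triangle's winding
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            if {int(a), int(b)} == {u, v}:
                succ[int(a)] = int(b)
                break
    loops = []
    remaining = set(succ)
    while remaining:
        start = min(remaining)
        loop = [start]
        remaining.discard(start)
        cur = succ[start]
        while cur != start:
            loop.append(cur)
            remaining.discard(cur)
            cur = succ[cur]
        loops.append(BoundaryLoop(vertices=loop))
    return loops


# -- I/O ---------------------------------------------------------------


def load_mesh(path, file_type=None) -> Mesh:
    """Load a mesh from STL (binary/ASCII), OBJ, or PLY.

    STL stores a triangle soup, so duplicate vertices within
    1e-9 x bounding-box diagonal are merged.  Non-manifold input raises
    :class:`NonManifoldError` naming the offending edges.
    """
    tm = trimesh.load_mesh(path, file_type=file_type, process=False)
    if isinstance(tm, trimesh.Scene):
        geoms = list(tm.geometry.values())
        if not geoms:
            raise ValueError(f"no mesh found in {path}")
        tm = trimesh.util.concatenate(geoms)
    if tm.vertices is None or len(tm.vertices) == 0:
        raise ValueError(f"empty mesh file: {path}")
    verts = np.asarray(tm.vertices, dtype=np.float64)
    faces = np.asarray(tm.faces, dtype=np.int64)
    diag = np.linalg.norm(verts.max(axis=0) - verts.min(axis=0))
    tol = 1e-9 * diag if diag > 0 else 1e-12
    verts, faces = merge_duplicate_vertices(verts, faces, tol)
    return Mesh(verts, faces)


def merge_duplicate_vertices(vertices, faces, tol):
    """Merge vertices closer than ``tol`` and drop degenerate faces."""
    if tol <= 0:
        keys = vertices
    else:
        keys = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(
        keys, axis=0, return_index=True, return_inverse=True
    )
    verts = vertices[first]
    faces = inverse[faces]
    ok = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 2] != faces[:, 0])
    )
    faces = faces[ok]
    # drop unreferenced vertices
    used = np.unique(faces)
    remap = -np.ones(len(verts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return verts[used], remap[faces]


def save_mesh(mesh: Mesh, path, file_type=None):
    """Write a mesh as STL, OBJ, or PLY (chosen from the extension)."""
    tm = trimesh.Trimesh(
        vertices=mesh.vertices, faces=mesh.faces, process=False
    )
    tm.export(path, file_type=file_type)
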