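"""Straight "lines" on a mesh surface and spatial-polygon selection.

Interactive region picking on a dental cast is replaced here by a
programmatic construction: a path between two surface points is traced
by repeatedly intersecting the current triangle with the normal
section, the plane through the current point spanned by the remaining
travel direction and the surface normal.  On a flat mesh this
reproduces the Euclidean segment exactly; on a curved mesh it yields
an approximate geodesic in time linear in the path length.  A closed
fence of such paths selects the triangles enclosed by it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh_core import Mesh
from .curvature import area_weighted_normal


class PathError(RuntimeError):
    """Tracing failed; carries the partial path in :attr:`partial`."""

    def __init__(self, message, partial=None):
        super().__init__(message)
        self.partial = partial


@dataclass
class SurfacePath:
    """Piecewise-linear path on the mesh surface.

    ``points`` are 3D positions; ``segment_faces[i]`` is the triangle
    containing the segment from ``points[i]`` to ``points[i+1]``.
    """

    points: list
    segment_faces: list

    def length(self):
        p = np.asarray(self.points)
        return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())

    def __len__(self):
        return len(self.points)


@dataclass
class SpatialPolygon:
    """A closed fence of surface paths and the triangles it encloses.

    ``enclosed_faces`` are the triangles whose three vertices all fall
    strictly inside the fence; ``region_faces`` is the full interior
    flood-fill component (including triangles touching the fence
    polyline with a vertex).
    """

    paths: list
    fence_faces: frozenset
    enclosed_faces: frozenset
    region_faces: frozenset = frozenset()


def _locate(mesh: Mesh, where):
    """Resolve a surface-point spec to (position, candidate faces).

    Accepts a vertex index or a ``(position, face_index)`` pair.
    """
    if isinstance(where, (int, np.integer)):
        return mesh.vertices[int(where)].copy(), set(mesh.vertex_faces(int(where)))
    pos, fi = where
    return np.asarray(pos, dtype=float).copy(), {int(fi)}


def _point_normal(mesh: Mesh, faces, fn):
    n = np.sum([fn[f] for f in faces], axis=0)
    norm = np.linalg.norm(n)
    return n / norm if norm > 0 else fn[next(iter(faces))]


def trace_line(mesh: Mesh, start, end, max_steps=None) -> SurfacePath:
    """Trace the straight surface "line" from ``start`` to ``end``.

    At each step the current triangle is cut by the normal section (the
    plane through the current point containing the direction to the
    destination and the local normal); among forward exit points the
    one with the smallest angle to the destination direction is chosen,
    ties resolved in favor of the farther point so progress is
    guaranteed.  Terminates when the current point and the destination
    share a triangle.
    """
    scale = mesh.bbox_diagonal()
    snap = 1e-9 * scale
    p_s, s_faces = _locate(mesh, start)
    p_e, e_faces = _locate(mesh, end)
    fn = mesh.face_normals()
    verts = mesh.vertices
    faces = mesh.faces
    if max_steps is None:
        max_steps = 4 * mesh.n_faces + 100

    points = [p_s]
    seg_faces = []
    cur = p_s
    cur_faces = set(s_faces)

    for _ in range(max_steps):
        common = cur_faces & e_faces
        if common:
            points.append(p_e)
            seg_faces.append(min(common))
            return SurfacePath(points=points, segment_faces=seg_faces)
        direction = p_e - cur
        dnorm = np.linalg.norm(direction)
        if dnorm < snap:
            return SurfacePath(points=points, segment_faces=seg_faces)
        direction = direction / dnorm
        normal = _point_normal(mesh, cur_faces, fn)
        m = np.cross(direction, normal)
        mn = np.linalg.norm(m)
        if mn < 1e-14:
            # travel direction parallel to the normal: perturb slightly
            m = np.cross(direction + 1e-9, normal)
            mn = np.linalg.norm(m)
        m = m / mn

        best = None  # (cos_angle, dist, q, face, edge)
        for f in cur_faces:
            tri = faces[f]
            for e0, e1 in ((0, 1), (1, 2), (2, 0)):
                a, b = int(tri[e0]), int(tri[e1])
                pa, pb = verts[a], verts[b]
                sa = float(np.dot(pa - cur, m))
                sb = float(np.dot(pb - cur, m))
                qs = []
                if abs(sa - sb) > 1e-300 and sa * sb <= 0:
                    t = sa / (sa - sb)
                    if 0.0 <= t <= 1.0:
                        qs.append(pa + t * (pb - pa))
                else:
                    # edge lies (nearly) in the plane: try both endpoints
                    if abs(sa) <= snap:
                        qs.append(pa.copy())
                    if abs(sb) <= snap:
                        qs.append(pb.copy())
                for q in qs:
                    step = q - cur
                    dist = np.linalg.norm(step)
                    if dist < snap:
                        continue
                    cosang = float(np.dot(step, direction)) / dist
                    if cosang <= 0:
                        continue
                    cand = (cosang, dist, q, f, (a, b))
                    if (
                        best is None
                        or cand[0] > best[0] + 1e-12
                        or (abs(cand[0] - best[0]) <= 1e-12 and cand[1] > best[1])
                    ):
                        best = cand
        if best is None:
            raise PathError(
                "tracing stalled: no forward exit from the current carrier",
                partial=SurfacePath(points=points, segment_faces=seg_faces),
            )
        _, _, q, f, (a, b) = best
        points.append(q)
        seg_faces.append(f)
        # next carrier: vertex if we hit one, else the edge's other face
        if np.linalg.norm(q - verts[a]) <= snap:
            cur_faces = set(mesh.vertex_faces(a))
        elif np.linalg.norm(q - verts[b]) <= snap:
            cur_faces = set(mesh.vertex_faces(b))
        else:
            efaces = set(mesh.edge_face_indices(a, b))
            nxt = efaces - {f}
            if not nxt:
                raise PathError(
                    "trajectory leaves the mesh through boundary edge "
                    f"({a}, {b})",
                    partial=SurfacePath(points=points, segment_faces=seg_faces),
                )
            cur_faces = nxt
        cur = q
    raise PathError(
        "tracing exceeded the step budget (cycle suspected)",
        partial=SurfacePath(points=points, segment_faces=seg_faces),
    )


def _point_segment_dist(p, s0, s1):
    d = s1 - s0
    L2 = float(d @ d)
    if L2 < 1e-300:
        return float(np.linalg.norm(p - s0))
    t = np.clip(float((p - s0) @ d) / L2, 0.0, 1.0)
    return float(np.linalg.norm(p - (s0 + t * d)))


def _segments_cross(p0, p1, q0, q1, tol):
    """Do two 3D segments intersect away from shared endpoints?"""
    for a, b in ((p0, q0), (p0, q1), (p1, q0), (p1, q1)):
        if np.linalg.norm(a - b) <= tol:
            return False
    d1 = p1 - p0
    d2 = q1 - q0
    n = np.cross(d1, d2)
    nn = np.linalg.norm(n)
    if nn < 1e-14:
        return False
    # closest points of the two lines
    w = q0 - p0
    s = float(np.dot(np.cross(w, d2), n)) / (nn * nn)
    t = float(np.dot(np.cross(w, d1), n)) / (nn * nn)
    if not (tol < s * np.linalg.norm(d1) < np.linalg.norm(d1) - tol):
        return False
    if not (tol < t * np.linalg.norm(d2) < np.linalg.norm(d2) - tol):
        return False
    c1 = p0 + s * d1
    c2 = q0 + t * d2
    return np.linalg.norm(c1 - c2) <= tol


def select_polygon(
    mesh: Mesh, anchors, seed_face=None
) -> SpatialPolygon:
    """Select the triangles enclosed by a closed fence of traced lines.

    The fence concatenates traced paths between consecutive anchors
    (cyclically).  Triangles the fence passes through form the barrier;
    the enclosed set is the flood-fill component of the face-adjacency
    graph grown from a seed triangle (by default the triangle nearest
    the anchor centroid) without crossing the barrier.
    """
    anchors = list(anchors)
    if len(anchors) < 3:
        raise ValueError("need at least 3 anchors")
    paths = []
    for i in range(len(anchors)):
        paths.append(trace_line(mesh, anchors[i], anchors[(i + 1) % len(anchors)]))

    scale = mesh.bbox_diagonal()
    fence_faces = set()
    by_face = {}
    segs = []
    for pi, path in enumerate(paths):
        for si in range(len(path.points) - 1):
            f = path.segment_faces[si]
            fence_faces.add(f)
            seg = (np.asarray(path.points[si]), np.asarray(path.points[si + 1]))
            by_face.setdefault(f, []).append((len(segs), seg))
            segs.append((pi, si))
    # fence self-intersection: only segments sharing a face can cross
    for f, items in by_face.items():
        for x in range(len(items)):
            for y in range(x + 1, len(items)):
                ia, (a0, a1) = items[x]
                ib, (b0, b1) = items[y]
                if abs(ia - ib) <= 1 or {ia, ib} == {0, len(segs) - 1}:
                    continue
                if _segments_cross(a0, a1, b0, b1, 1e-9 * scale):
                    raise PathError("fence self-intersects")

    # vertices lying on the fence polyline (candidates are confined to
    # the fence faces) and edges the fence runs along: both block the
    # interior flood fill
    tol = 1e-9 * scale
    all_segs = [s for items in by_face.values() for _, s in items]
    cand_verts = sorted({int(v) for f in fence_faces for v in mesh.faces[f]})
    fence_verts = {
        v
        for v in cand_verts
        if any(
            _point_segment_dist(mesh.vertices[v], s0, s1) <= tol
            for s0, s1 in all_segs
        )
    }
    barrier_edges = set()
    for v in fence_verts:
        for u in mesh.vertex_neighbors(v):
            if u in fence_verts:
                mid = 0.5 * (mesh.vertices[v] + mesh.vertices[u])
                if any(
                    _point_segment_dist(mid, s0, s1) <= tol
                    for s0, s1 in all_segs
                ):
                    barrier_edges.add((min(u, v), max(u, v)))

    centroids = mesh.vertices[mesh.faces].mean(axis=1)
    if seed_face is None:
        target = np.mean([_locate(mesh, a)[0] for a in anchors], axis=0)
        order = np.argsort(np.linalg.norm(centroids - target, axis=1))
        seed_face = -1
        for f in order:
            if int(f) not in fence_faces:
                seed_face = int(f)
                break
    if seed_face < 0 or seed_face in fence_faces:
        return SpatialPolygon(
            paths=paths,
            fence_faces=frozenset(fence_faces),
            enclosed_faces=frozenset(),
        )

    region = {seed_face}
    frontier = [seed_face]
    while frontier:
        f = frontier.pop()
        tri = mesh.faces[f]
        for e0, e1 in ((0, 1), (1, 2), (2, 0)):
            a, b = int(tri[e0]), int(tri[e1])
            if (min(a, b), max(a, b)) in barrier_edges:
                continue
            for g in mesh.edge_face_indices(a, b):
                if g != f and g not in region and g not in fence_faces:
                    region.add(g)
                    frontier.append(g)
    if len(region) + len(fence_faces) >= mesh.n_faces:
        # a tiny fence (a few triangles) encloses no complete triangle:
        # that is an empty selection, not a failure
        if len(fence_faces) <= 3 * len(anchors):
            return SpatialPolygon(
                paths=paths,
                fence_faces=frozenset(fence_faces),
                enclosed_faces=frozenset(),
                region_faces=frozenset(),
            )
        raise PathError("fence does not separate the surface")
    enclosed = {
        f
        for f in region
        if not any(int(v) in fence_verts for v in mesh.faces[f])
    }
    return SpatialPolygon(
        paths=paths,
        fence_faces=frozenset(fence_faces),
        enclosed_faces=frozenset(enclosed),
        region_faces=frozenset(region),
    )
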