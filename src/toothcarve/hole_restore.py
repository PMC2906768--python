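"""Single-tooth shape restoration.

After a fusion region between two adjoining teeth is removed, the
resulting hole is a saddle shared by both teeth.  Filling it as a whole
would average the two teeth's boundary information into one patch, so
the hole is first **bridged** into two per-tooth subholes using the
occlusal plane as reference, then each subhole is filled in stages:

* ``P^min`` - spanning triangulation of the subhole boundary by a
  locally optimized weight rule (advancing front with an ordered
  weight queue, O(N log N));
* ``P^refine`` - 1-to-3 centroid splitting with Delaunay-style edge
  relaxation until the patch density approximates the surrounding mesh;
* ``P^deform`` - k-harmonic fairing (discrete Euler-Lagrange equation
  Delta^k x = 0 with boundary constraints, k = 2 thin plate by
  default);
* ``P^final = P^refine + lambda (P^deform - P^refine)`` - the
  deformation degree lambda is decreased stepwise from 1 until the two
  restored patches no longer interfere (lambda is kept in [0.8, 1]).
"""

from __future__ import annotations

import heapq
import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh_core import Mesh, BoundaryLoop, neighborhood
from .curvature import cotangent_weights

log = logging.getLogger(__name__)

NEG_INF = float("-inf")


# ---------------------------------------------------------------------
# occlusal plane
# ---------------------------------------------------------------------


@dataclass
class OcclusalPlane:
    """Total-least-squares plane through four cusp reference points.

    ``normal . x = offset``; the normal is oriented toward the crowns
    (positive dot with the ``up_hint`` used at fit time).
    """

    normal: np.ndarray
    offset: float
    points: np.ndarray

    def signed_distance(self, x):
        return np.asarray(x) @ self.normal - self.offset

    def distance(self, x):
        return np.abs(self.signed_distance(x))


def fit_occlusal_plane(points, up_hint=(0.0, 0.0, 1.0)) -> OcclusalPlane:
    """Fit the plane minimizing squared orthogonal distances to 4 points."""
    pts = np.asarray(points, dtype=float)
    if pts.shape != (4, 3):
        raise ValueError("expected exactly four 3D reference points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise ValueError("reference points are collinear or coincident")
    normal = vt[2]
    if np.dot(normal, np.asarray(up_hint, dtype=float)) < 0:
        normal = -normal
    return OcclusalPlane(
        normal=normal, offset=float(normal @ centroid), points=pts
    )


# ---------------------------------------------------------------------
# subhole division
# ---------------------------------------------------------------------


@dataclass
class SubholePair:
    """A saddle hole split at its two occlusal-distance maxima.

    ``sub1``/``sub2`` are ordered cyclic vertex-id lists; both contain
    the two bridge endpoints, and the bridge edge belongs to both.
    """

    parent: list
    sub1: list
    sub2: list
    bridge: tuple


def _cyclic_local_maxima(values):
    n = len(values)
    out = []
    for i in range(n):
        a = values[(i - 1) % n]
        b = values[(i + 1) % n]
        if values[i] > a and values[i] >= b:
            out.append(i)
    return out


def bridge_hole(mesh: Mesh, loop: BoundaryLoop, plane: OcclusalPlane) -> SubholePair:
    """Split a saddle hole boundary at the two points farthest from the
    occlusal plane (one on the buccal and one on the lingual arc).

    The two strongest cyclic local maxima of the distance-to-plane
    profile are taken as bridge endpoints; the bridge edge joins them
    and closes each of the two subloops.
    """
    verts = list(loop.vertices)
    n = len(verts)
    if n < 6:
        raise ValueError("loop too short to bridge (need >= 6 vertices)")
    dist = [float(plane.distance(mesh.vertices[v])) for v in verts]
    maxima = _cyclic_local_maxima(dist)
    if len(maxima) < 2:
        raise ValueError("no saddle: fewer than two local distance maxima")
    maxima.sort(key=lambda i: -dist[i])
    a = maxima[0]
    # the second endpoint must lie on the opposite arc (buccal vs
    # lingual side), not next to the first peak
    min_sep = max(2, n // 4)

    def sep(x):
        return min((x - a) % n, (a - x) % n)

    far = [x for x in maxima[1:] if sep(x) >= min_sep]
    if not far:
        far = [x for x in maxima[1:] if sep(x) >= 2]
    if not far:
        raise ValueError("degenerate split: the two maxima are adjacent")
    a, b = sorted((a, far[0]))
    sub1 = verts[a : b + 1]
    sub2 = verts[b:] + verts[: a + 1]
    return SubholePair(
        parent=verts,
        sub1=sub1,
        sub2=sub2,
        bridge=(verts[a], verts[b]),
    )


# ---------------------------------------------------------------------
# spanning triangulation (weight rule)
# ---------------------------------------------------------------------


@dataclass
class Patch:
    """A filling surface patch.

    The first ``n_boundary`` vertices are the hole-boundary vertices in
    loop order (their positions are shared with the surrounding mesh
    and never move); any further vertices are interior, added by
    refinement.  ``mesh_vertex_ids`` maps boundary vertices to global
    mesh indices when the patch is attached to a mesh.
    """

    vertices: np.ndarray
    faces: np.ndarray
    n_boundary: int
    mesh_vertex_ids: np.ndarray | None = None

    def copy(self):
        return Patch(
            vertices=self.vertices.copy(),
            faces=self.faces.copy(),
            n_boundary=self.n_boundary,
            mesh_vertex_ids=None
            if self.mesh_vertex_ids is None
            else self.mesh_vertex_ids.copy(),
        )

    def triangles(self):
        return self.vertices[self.faces]


def _cross_rows(A, B):
    """Row-wise cross product of (m, 3) arrays (fast path)."""
    out = np.empty(np.broadcast_shapes(A.shape, B.shape))
    out[..., 0] = A[..., 1] * B[..., 2] - A[..., 2] * B[..., 1]
    out[..., 1] = A[..., 2] * B[..., 0] - A[..., 0] * B[..., 2]
    out[..., 2] = A[..., 0] * B[..., 1] - A[..., 1] * B[..., 0]
    return out


def _angle(p, a, b):
    """Angle at p between directions toward a and b."""
    u = a - p
    v = b - p
    return math.atan2(
        np.linalg.norm(np.cross(u, v)), float(np.dot(u, v))
    )


class TriangulationState:
    """Advancing-front state for the weight-rule spanning triangulation.

    Tracks the working cyclic boundary, the per-vertex adjacent-angle
    sum A(v), the incident-triangle count |NeiT1|, incident edges (for
    the non-intersection projection test), and accumulated patch
    triangles.  When the hole sits in a mesh, those quantities start
    from the surrounding mesh triangles; a standalone loop starts from
    zero.
    """

    def __init__(
        self,
        positions,
        radius=None,
        alpha=1.2,
        env=None,
        extra_triangles=(),
        boundary=None,
        flip_orientation=False,
    ):
        self.pos = np.asarray(positions, dtype=float)
        n = len(self.pos)
        self.alpha = alpha
        if radius is None:
            lo = self.pos.min(axis=0)
            hi = self.pos.max(axis=0)
            radius = 0.5 * float(np.linalg.norm(hi - lo))
        self.radius = radius
        self.flip = flip_orientation
        self.tol = 1e-12 * max(radius, 1e-300)

        order = list(range(n)) if boundary is None else list(boundary)
        self.alive = [False] * n
        self.next = [-1] * n
        self.prev = [-1] * n
        for x, i in enumerate(order):
            self.alive[i] = True
            self.next[i] = order[(x + 1) % len(order)]
            self.prev[i] = order[(x - 1) % len(order)]
        self.n_alive = len(order)

        self.A = np.zeros(n)
        self.neiT = np.zeros(n, dtype=int)
        self.nsum = np.zeros((n, 3))
        # incident edges: spokes (positions of edge neighbors) and the
        # far edges of incident triangles, both used by the projection
        # test
        self.adj = [[] for _ in range(n)]
        self.opp = [[] for _ in range(n)]
        for i in order:
            self.adj[i].append(self.pos[self.next[i]])
            self.adj[i].append(self.pos[self.prev[i]])
        if env is not None:
            for i in range(n):
                self.A[i] = env["A0"][i]
                self.neiT[i] = env["neiT0"][i]
                self.nsum[i] = env["nsum0"][i]
                self.adj[i] = list(env["adj0"][i]) + self.adj[i]
                self.opp[i] = list(env["opp0"][i])
        self.triangles = []
        for tri in extra_triangles:
            self._account_triangle_positions(np.asarray(tri))

    def _account_triangle_positions(self, tri):
        """Fold an externally added triangle (3x3 positions) into the
        per-vertex bookkeeping wherever its corners coincide with
        boundary vertices."""
        for ci in range(3):
            p = tri[ci]
            hits = np.flatnonzero(
                np.linalg.norm(self.pos - p, axis=1) <= 10 * self.tol
            )
            for v in hits:
                q, r = tri[(ci + 1) % 3], tri[(ci + 2) % 3]
                self.A[v] += _angle(p, q, r)
                self.neiT[v] += 1
                self.nsum[v] += np.cross(q - p, r - p)
                self.adj[v].extend([q, r])
                self.opp[v].append((q, r))

    # -- weight ------------------------------------------------------

    def _projection_ok(self, j, i, k):
        """Non-intersection projection condition for candidate (j,i,k).

        The candidate's new edge (v_j, v_k), projected together with
        the existing incident edges onto each endpoint's tangent plane,
        must not cross any of them except at shared vertices.
        """
        pj, pi, pk = self.pos[j], self.pos[i], self.pos[k]
        tri_n = np.cross(pi - pj, pk - pj)
        tol = self.tol
        for v in (j, i, k):
            nv = self.nsum[v]
            nn = np.linalg.norm(nv)
            if nn < 1e-300:
                nv = tri_n
                nn = np.linalg.norm(nv)
                if nn < 1e-300:
                    continue
            nv = nv / nn
            origin = self.pos[v]
            m = len(self.adj[v]) + len(self.opp[v])
            if m == 0:
                continue
            b0 = np.empty((m, 3))
            b1 = np.empty((m, 3))
            na = len(self.adj[v])
            if na:
                b0[:na] = origin
                b1[:na] = self.adj[v]
            for x, (q, r) in enumerate(self.opp[v]):
                b0[na + x] = q
                b1[na + x] = r

            def proj(x):
                d = x - origin
                return d - (d @ nv)[..., None] * nv if d.ndim > 1 else d - float(d @ nv) * nv

            a0, a1 = proj(pj), proj(pk)
            B0, B1 = proj(b0), proj(b1)
            # skip segments sharing an endpoint with the new edge
            shared = np.zeros(m, dtype=bool)
            for a in (a0, a1):
                shared |= np.linalg.norm(B0 - a, axis=1) <= 2 * tol
                shared |= np.linalg.norm(B1 - a, axis=1) <= 2 * tol
            if shared.all():
                continue
            d1 = a1 - a0
            D2 = B1 - B0
            N = _cross_rows(np.broadcast_to(d1, D2.shape), D2)
            nn2 = np.einsum("ij,ij->i", N, N)
            W = B0 - a0
            valid = (~shared) & (nn2 > 1e-300)
            if not valid.any():
                continue
            s = np.einsum("ij,ij->i", _cross_rows(W, D2), N)
            t = np.einsum(
                "ij,ij->i", _cross_rows(W, np.broadcast_to(d1, W.shape)), N
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                s = s / nn2
                t = t / nn2
            eps = 1e-9
            cand = valid & (s > eps) & (s < 1 - eps) & (t > eps) & (t < 1 - eps)
            if cand.any():
                c1 = a0 + s[cand, None] * d1
                c2 = B0[cand] + t[cand, None] * D2[cand]
                gap = np.linalg.norm(c1 - c2, axis=1)
                if np.any(gap <= max(tol, 1e-9 * np.linalg.norm(d1))):
                    return False
        return True

    def weight(self, i):
        """Weight of the candidate triangle (prev(i), i, next(i)).

        Case priority: -inf when the projection condition fails;
        l_bigger = (|NeiT1(i)|/8) R_C when the vertex already carries
        more than 8 incident triangles (remove it first); l_less =
        -(pi/A(v_i)) R_C when its adjacent-angle sum is a sharp-but-
        open corner 0 < A < alpha*pi; else minus the perimeter.
        """
        j, k = self.prev[i], self.next[i]
        if not self._projection_ok(j, i, k):
            return NEG_INF
        if self.neiT[i] > 8:
            return (self.neiT[i] / 8.0) * self.radius
        a = self.A[i]
        if 0.0 < a < self.alpha * math.pi:
            return -(math.pi / a) * self.radius
        pj, pi, pk = self.pos[j], self.pos[i], self.pos[k]
        return -(
            np.linalg.norm(pi - pj)
            + np.linalg.norm(pk - pi)
            + np.linalg.norm(pk - pj)
        )

    def perimeter(self, i):
        j, k = self.prev[i], self.next[i]
        pj, pi, pk = self.pos[j], self.pos[i], self.pos[k]
        return float(
            np.linalg.norm(pi - pj)
            + np.linalg.norm(pk - pi)
            + np.linalg.norm(pk - pj)
        )

    # -- step --------------------------------------------------------

    def clip_ear(self, i):
        """Insert the candidate triangle at apex ``i`` and remove ``i``
        from the working boundary."""
        j, k = self.prev[i], self.next[i]
        pj, pi, pk = self.pos[j], self.pos[i], self.pos[k]
        self.triangles.append((k, i, j) if self.flip else (j, i, k))
        self.A[j] += _angle(pj, pi, pk)
        self.A[i] += _angle(pi, pj, pk)
        self.A[k] += _angle(pk, pi, pj)
        for v in (j, i, k):
            self.neiT[v] += 1
        nvec = np.cross(pi - pj, pk - pj)
        if self.flip:
            nvec = -nvec
        for v in (j, i, k):
            self.nsum[v] += nvec
        self.adj[j].append(pk)
        self.adj[k].append(pj)
        self.opp[j].append((pi, pk))
        self.opp[i].append((pj, pk))
        self.opp[k].append((pj, pi))
        self.alive[i] = False
        self.next[j] = k
        self.prev[k] = j
        self.n_alive -= 1
        return j, k


def _proj_segments_cross(a0, a1, b0, b1, tol):
    """Do two (projected, coplanar) segments cross away from shared
    endpoints?"""
    for p, q in ((a0, b0), (a0, b1), (a1, b0), (a1, b1)):
        if np.linalg.norm(p - q) <= 2 * tol:
            return False
    d1 = a1 - a0
    d2 = b1 - b0
    n = np.cross(d1, d2)
    nn = float(n @ n)
    if nn < 1e-300:
        return False
    w = b0 - a0
    s = float(np.cross(w, d2) @ n) / nn
    t = float(np.cross(w, d1) @ n) / nn
    eps = 1e-9
    if not (eps < s < 1 - eps and eps < t < 1 - eps):
        return False
    return np.linalg.norm((a0 + s * d1) - (b0 + t * d2)) <= max(
        tol, 1e-9 * np.linalg.norm(d1)
    )


def triangulate_boundary(
    loop,
    mesh: Mesh | None = None,
    radius=None,
    alpha=1.2,
    flip_orientation=False,
    extra_triangles=(),
) -> Patch:
    """Spanning triangulation P^min of a simple closed boundary.

    ``loop`` is a :class:`BoundaryLoop` (with ``mesh``) or an (n, 3)
    array of cyclically ordered positions.  Produces exactly n - 2
    triangles over exactly the n boundary vertices.  The ordered weight
    set is kept in a lazy-deletion binary heap, so each of the n - 2
    ear insertions costs O(log n).  Ties on the maximum weight go to
    the lowest boundary index.  If every remaining weight is -inf the
    least-perimeter candidate is accepted once, ignoring the projection
    test (logged), which prevents deadlock.
    """
    if isinstance(loop, BoundaryLoop):
        if mesh is None:
            raise ValueError("a BoundaryLoop needs its mesh")
        vertex_ids = np.asarray(loop.vertices, dtype=np.int64)
        positions = mesh.vertices[vertex_ids]
        env = boundary_environment(mesh, loop.vertices)
    else:
        positions = np.asarray(loop, dtype=float)
        vertex_ids = None
        env = None
    n = len(positions)
    if n < 3:
        raise ValueError("loop must have at least 3 vertices")

    state = TriangulationState(
        positions,
        radius=radius,
        alpha=alpha,
        env=env,
        extra_triangles=extra_triangles,
        flip_orientation=flip_orientation,
    )
    version = [0] * n
    heap = []
    for i in range(n):
        heapq.heappush(heap, (-state.weight(i), i, version[i]))

    def push(i):
        version[i] += 1
        heapq.heappush(heap, (-state.weight(i), i, version[i]))

    while state.n_alive >= 3:
        # pop the freshest maximum weight
        best = None
        while heap:
            negw, i, ver = heap[0]
            if not state.alive[i] or ver != version[i]:
                heapq.heappop(heap)
                continue
            best = (negw, i)
            break
        if best is None or best[0] == math.inf:
            # all candidates fail the projection test: fall back to the
            # least-perimeter choice once
            alive = [x for x in range(n) if state.alive[x]]
            i = min(alive, key=lambda x: (state.perimeter(x), x))
            log.warning(
                "triangulation deadlock: accepting least-perimeter ear at "
                "boundary index %d without the projection test",
                i,
            )
        else:
            heapq.heappop(heap)
            i = best[1]
        j, k = state.clip_ear(i)
        if state.n_alive >= 3:
            # the clip changes A/NeiT/incident edges of j and k, which
            # enter the weights of every remaining triple containing
            # them: those centered at prev(j), j, k, next(k)
            for x in {state.prev[j], j, k, state.next[k]}:
                if state.alive[x]:
                    push(x)

    faces = np.asarray(state.triangles, dtype=np.int64)
    return Patch(
        vertices=positions.copy(),
        faces=faces,
        n_boundary=n,
        mesh_vertex_ids=vertex_ids,
    )


def boundary_environment(mesh: Mesh, loop_vertices):
    """Per-loop-vertex surroundings: angle sums, triangle counts,
    incident edges, and normal sums taken from the existing mesh."""
    n = len(loop_vertices)
    env = {
        "A0": np.zeros(n),
        "neiT0": np.zeros(n, dtype=int),
        "nsum0": np.zeros((n, 3)),
        "adj0": [[] for _ in range(n)],
        "opp0": [[] for _ in range(n)],
    }
    verts = mesh.vertices
    for x, v in enumerate(loop_vertices):
        for fi in mesh.vertex_faces(v):
            f = mesh.faces[fi]
            others = [int(y) for y in f if y != v]
            p, q, r = verts[v], verts[others[0]], verts[others[1]]
            env["A0"][x] += _angle(p, q, r)
            env["neiT0"][x] += 1
            env["nsum0"][x] += np.cross(verts[f[1]] - verts[f[0]],
                                        verts[f[2]] - verts[f[0]])
            env["opp0"][x].append((q.copy(), r.copy()))
        for u in mesh.vertex_neighbors(v):
            env["adj0"][x].append(verts[u].copy())
    return env


# ---------------------------------------------------------------------
# refinement
# ---------------------------------------------------------------------


def _patch_edge_faces(faces):
    ef = {}
    for fi, (a, b, c) in enumerate(faces):
        for u, v in ((a, b), (b, c), (c, a)):
            ef.setdefault((min(u, v), max(u, v)), []).append(fi)
    return ef


def refine_patch(
    patch: Patch, target_edge_length: float, c: float = 1.5, max_rounds: int = 60
) -> Patch:
    """Densify P^min to P^refine by 1-to-3 centroid splits with
    Delaunay-style edge relaxation.

    Triangles whose mean edge length exceeds ``c`` times the target
    (the surrounding-mesh average) are split at their centroid; after
    each split round, interior edges whose opposite angles sum beyond
    pi are flipped.  Boundary edges are never flipped.  Iterates to a
    fixpoint: splits strictly shrink triangles and flips strictly
    decrease the Delaunay energy.
    """
    verts = [v.copy() for v in patch.vertices]
    faces = [tuple(int(x) for x in f) for f in patch.faces]
    nb = patch.n_boundary

    def mean_edge(f):
        a, b, cc = f
        pa, pb, pc = verts[a], verts[b], verts[cc]
        return (
            np.linalg.norm(pa - pb)
            + np.linalg.norm(pb - pc)
            + np.linalg.norm(pc - pa)
        ) / 3.0

    threshold = c * target_edge_length
    # never create spokes much shorter than the target density: this
    # bounds the refinement when a boundary (e.g. bridge) edge is
    # longer than the target and cannot be split or flipped away
    min_spoke = 0.45 * target_edge_length
    for _ in range(max_rounds):
        split_any = False
        for fi in range(len(faces)):
            f = faces[fi]
            if mean_edge(f) <= threshold:
                continue
            a, b, cc = f
            centroid = (verts[a] + verts[b] + verts[cc]) / 3.0
            if min(
                np.linalg.norm(centroid - verts[x]) for x in (a, b, cc)
            ) < min_spoke:
                continue
            m = len(verts)
            verts.append(centroid)
            faces[fi] = (a, b, m)
            faces.append((b, cc, m))
            faces.append((cc, a, m))
            split_any = True
        if not split_any:
            break
        _relax_delaunay(verts, faces, nb)
    return Patch(
        vertices=np.asarray(verts),
        faces=np.asarray(faces, dtype=np.int64),
        n_boundary=nb,
        mesh_vertex_ids=None
        if patch.mesh_vertex_ids is None
        else patch.mesh_vertex_ids.copy(),
    )


def _relax_delaunay(verts, faces, n_boundary, max_passes=40):
    """Flip interior edges whose opposite angles sum beyond pi.

    Faces already modified in a pass are left alone until the next
    pass (the cached adjacency would be stale), and a flip is skipped
    when the replacement diagonal already exists elsewhere.
    """
    for _ in range(max_passes):
        ef = _patch_edge_faces(faces)
        dirty = set()
        flipped = 0
        for (a, b), fs in ef.items():
            if len(fs) != 2:
                continue  # patch-boundary edge: never flipped
            f0, f1 = fs
            if f0 in dirty or f1 in dirty:
                continue
            c0 = [x for x in faces[f0] if x not in (a, b)][0]
            c1 = [x for x in faces[f1] if x not in (a, b)][0]
            if (min(c0, c1), max(c0, c1)) in ef:
                continue  # would duplicate an existing edge
            ang0 = _angle(verts[c0], verts[a], verts[b])
            ang1 = _angle(verts[c1], verts[a], verts[b])
            if ang0 + ang1 <= math.pi + 1e-9:
                continue
            # keep winding: orient by the directed occurrence of the
            # old diagonal in f0
            f0v = faces[f0]
            for u, v in ((f0v[0], f0v[1]), (f0v[1], f0v[2]), (f0v[2], f0v[0])):
                if {u, v} == {a, b}:
                    a2, b2 = u, v
                    break
            faces[f0] = (a2, c1, c0)
            faces[f1] = (c1, b2, c0)
            dirty.add(f0)
            dirty.add(f1)
            flipped += 1
        if flipped == 0:
            break


# ---------------------------------------------------------------------
# k-harmonic reshaping
# ---------------------------------------------------------------------


def glue_patches(mesh: Mesh, patches):
    """Stitch patches onto the mesh sharing boundary vertex ids.

    Returns the combined mesh, the global interior-vertex ids of each
    patch, and the per-patch local->global index maps.
    """
    verts = [mesh.vertices]
    faces = [mesh.faces]
    offset = mesh.n_vertices
    interiors = []
    maps = []
    for p in patches:
        if p.mesh_vertex_ids is None:
            raise ValueError("patch is not attached to the mesh")
        n_int = len(p.vertices) - p.n_boundary
        local2global = np.empty(len(p.vertices), dtype=np.int64)
        local2global[: p.n_boundary] = p.mesh_vertex_ids
        local2global[p.n_boundary :] = offset + np.arange(n_int)
        verts.append(p.vertices[p.n_boundary :])
        faces.append(local2global[p.faces])
        interiors.append(local2global[p.n_boundary :])
        maps.append(local2global)
        offset += n_int
    combined = Mesh(
        np.vstack(verts), np.vstack(faces), validate=False
    )
    return combined, interiors, maps


def laplacian_matrix(mesh: Mesh, weights=None):
    """Cotangent Laplacian with the 1-ring-area scaling 2/Area(v_i)."""
    if weights is None:
        weights = cotangent_weights(mesh)
    n = mesh.n_vertices
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for (i, j), w in weights.edge_weight.items():
        rows += [i, j]
        cols += [j, i]
        vals += [-w, -w]
        diag[i] += w
        diag[j] += w
    rows += list(range(n))
    cols += list(range(n))
    vals += list(diag)
    L = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    area = np.maximum(weights.ring_area, 1e-300)
    return sp.diags(2.0 / area) @ L


def reshape_patch(mesh: Mesh, patch, k: int = 2):
    """Fair the patch interior by solving Delta^k x = 0, P^refine -> P^deform.

    The patch (or list of patches) is glued into the mesh; cotangent
    weights and ring areas are taken from the glued P^refine geometry
    and frozen.  Interior free vertices solve the sparse constrained
    k-harmonic system; boundary continuity C^{k-1} is realized by the
    surrounding constraint vertices entering the k-ring stencil.
    """
    if k not in (1, 2, 3):
        raise ValueError("fairing order k must be 1, 2, or 3")
    single = isinstance(patch, Patch)
    patches = [patch] if single else list(patch)
    combined, interiors, maps = glue_patches(mesh, patches)
    free = np.concatenate(interiors) if interiors else np.array([], dtype=int)
    if len(free) == 0:
        return patch if single else [p.copy() for p in patches]
    L = laplacian_matrix(combined)
    A = L
    for _ in range(k - 1):
        A = L @ A
    n = combined.n_vertices
    mask = np.zeros(n, dtype=bool)
    mask[free] = True
    cons = np.flatnonzero(~mask)
    A = A.tocsr()
    Aff = A[free][:, free].tocsc()
    Afc = A[free][:, cons]
    rhs = -Afc @ combined.vertices[cons]
    try:
        solve = spla.factorized(Aff)
    except RuntimeError as exc:
        raise ValueError(f"singular k-harmonic system: {exc}") from exc
    x = np.column_stack([solve(rhs[:, d]) for d in range(3)])
    resid = np.linalg.norm(Aff @ x - rhs)
    scale = combined.bbox_diagonal()
    if resid > 1e-8 * max(scale, 1e-300) * max(1.0, np.linalg.norm(rhs)):
        raise ValueError(f"k-harmonic solve residual too large: {resid:g}")
    positions = combined.vertices.copy()
    positions[free] = x
    out = []
    for p, l2g in zip(patches, maps):
        q = p.copy()
        q.vertices = positions[l2g]
        out.append(q)
    return out[0] if single else out


def blend_patch(refine: Patch, deform: Patch, lam: float) -> Patch:
    """P^final = P^refine + lambda (P^deform - P^refine), 0 < lambda <= 1."""
    if not 0.0 < lam <= 1.0:
        raise ValueError("lambda must be in (0, 1]")
    if refine.faces.shape != deform.faces.shape or not np.array_equal(
        refine.faces, deform.faces
    ):
        raise ValueError("P^refine and P^deform must share connectivity")
    out = refine.copy()
    out.vertices = refine.vertices + lam * (deform.vertices - refine.vertices)
    return out


# ---------------------------------------------------------------------
# triangle-triangle interference
# ---------------------------------------------------------------------


def _tri_interval(proj, dists, tol):
    pts = []
    for i, j in ((0, 1), (1, 2), (2, 0)):
        di, dj = dists[i], dists[j]
        if abs(di) <= tol:
            pts.append(proj[i])
        if di * dj < 0 and abs(di) > tol and abs(dj) > tol:
            t = di / (di - dj)
            pts.append(proj[i] + t * (proj[j] - proj[i]))
    if not pts:
        return None
    return min(pts), max(pts)


def _point_in_tri_2d(p, tri, tol):
    s = 0
    for i in range(3):
        a, b = tri[i], tri[(i + 1) % 3]
        cr = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
        if cr < -tol:
            s |= 1
        elif cr > tol:
            s |= 2
    return s != 3


def _seg_2d_cross(a0, a1, b0, b1, tol):
    d1 = a1 - a0
    d2 = b1 - b0
    den = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(den) < 1e-300:
        return False
    w = b0 - a0
    s = (w[0] * d2[1] - w[1] * d2[0]) / den
    t = (w[0] * d1[1] - w[1] * d1[0]) / den
    return -tol <= s <= 1 + tol and -tol <= t <= 1 + tol


def tri_tri_intersect(t1, t2, tol=1e-12):
    """Do two 3D triangles intersect? Moller-style interval test with a
    coplanar 2D fallback, toleranced at ``tol`` (relative to unit
    scale)."""
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    scale = max(1.0, np.abs(np.concatenate([t1, t2])).max())
    tol_s = tol * scale
    n2 = np.cross(t2[1] - t2[0], t2[2] - t2[0])
    d1 = (t1 - t2[0]) @ n2
    if np.all(d1 > tol_s * np.linalg.norm(n2)) or np.all(
        d1 < -tol_s * np.linalg.norm(n2)
    ):
        return False
    n1 = np.cross(t1[1] - t1[0], t1[2] - t1[0])
    d2 = (t2 - t1[0]) @ n1
    if np.all(d2 > tol_s * np.linalg.norm(n1)) or np.all(
        d2 < -tol_s * np.linalg.norm(n1)
    ):
        return False
    nn1 = np.linalg.norm(n1)
    nn2 = np.linalg.norm(n2)
    if nn1 < 1e-300 or nn2 < 1e-300:
        return False  # degenerate triangle
    if np.max(np.abs(d1)) <= tol_s * nn2 and np.max(np.abs(d2)) <= tol_s * nn1:
        # coplanar: project onto the dominant axis plane
        axis = int(np.argmax(np.abs(n1)))
        keep = [a for a in range(3) if a != axis]
        a2 = t1[:, keep]
        b2 = t2[:, keep]
        for i in range(3):
            for j in range(3):
                if _seg_2d_cross(
                    a2[i], a2[(i + 1) % 3], b2[j], b2[(j + 1) % 3], tol
                ):
                    return True
        return _point_in_tri_2d(a2[0], b2, tol_s) or _point_in_tri_2d(
            b2[0], a2, tol_s
        )
    D = np.cross(n1, n2)
    i1 = _tri_interval(t1 @ D, d1 / nn2, tol_s)
    i2 = _tri_interval(t2 @ D, d2 / nn1, tol_s)
    if i1 is None or i2 is None:
        return False
    return i1[0] <= i2[1] + tol_s and i2[0] <= i1[1] + tol_s


def patches_intersect(a: Patch, b: Patch, tol=1e-12):
    """Does any triangle of ``a`` intersect any triangle of ``b``?

    Pairs sharing a vertex (by position) are excluded, so patches
    meeting along a common bridge edge do not count as interfering.
    Returns (hit, witness) with the witness face-index pair or None.
    """
    ta = a.triangles()
    tb = b.triangles()
    scale = max(
        np.abs(a.vertices).max(initial=1.0), np.abs(b.vertices).max(initial=1.0)
    )
    share_tol = 1e-9 * scale
    # AABB prefilter
    amin, amax = ta.min(axis=1), ta.max(axis=1)
    bmin, bmax = tb.min(axis=1), tb.max(axis=1)
    pad = share_tol
    for i in range(len(ta)):
        cand = np.flatnonzero(
            np.all(amin[i] <= bmax + pad, axis=1)
            & np.all(bmin <= amax[i] + pad, axis=1)
        )
        for j in cand:
            shared = False
            for pa in ta[i]:
                if np.any(np.linalg.norm(tb[j] - pa, axis=1) <= share_tol):
                    shared = True
                    break
            if shared:
                continue
            if tri_tri_intersect(ta[i], tb[j], tol=tol):
                return True, (int(i), int(j))
    return False, None


# ---------------------------------------------------------------------
# full restoration pipeline
# ---------------------------------------------------------------------


class InterferenceError(RuntimeError):
    """Patches still interfere at the lambda floor; carries both."""

    def __init__(self, message, patches):
        super().__init__(message)
        self.patches = patches


def surrounding_edge_length(mesh: Mesh, loop_vertices, rings: int = 2):
    """Mean edge length of the mesh triangles within ``rings`` rings of
    the hole boundary."""
    near = set()
    for v in loop_vertices:
        near |= neighborhood(mesh, v, rings).members
    lengths = []
    for i in near:
        for j in mesh.vertex_neighbors(i):
            if j in near and i < j:
                lengths.append(
                    np.linalg.norm(mesh.vertices[i] - mesh.vertices[j])
                )
    return float(np.mean(lengths))


def restore_hole(
    mesh: Mesh,
    loop: BoundaryLoop,
    plane: OcclusalPlane,
    k: int = 2,
    lam_max: float = 1.0,
    tau: float = 0.01,
    lam_floor: float = 0.8,
    density_factor: float = 1.5,
):
    """Restore a fusion-region hole as two independent tooth patches.

    bridge -> per-subhole spanning triangulation -> refinement ->
    k-harmonic reshaping -> lambda blending, decreasing lambda from
    ``lam_max`` by ``tau`` until the two patches stop interfering.
    Returns ``(patch1, patch2, new_mesh, lam)``; raises
    :class:`InterferenceError` if interference persists at the lambda
    floor.
    """
    if tau > 0.01:
        raise ValueError("adjustment step tau must not exceed 0.01")
    if not 0 < lam_max <= 1.0:
        raise ValueError("lambda_max must be in (0, 1]")
    pair = bridge_hole(mesh, loop, plane)
    target = surrounding_edge_length(mesh, loop.vertices)

    # subdivide the bridge edge to the surrounding density: the chain
    # vertices are shared boundary constraints of both subhole patches,
    # so the two restored teeth meet along a well-sampled seam instead
    # of one long edge
    pa = mesh.vertices[pair.bridge[0]]
    pb = mesh.vertices[pair.bridge[1]]
    n_seg = max(1, int(round(np.linalg.norm(pb - pa) / target)))
    chain_pts = [
        pa + (pb - pa) * (s / n_seg) for s in range(1, n_seg)
    ]
    if chain_pts:
        chain_ids = list(
            range(mesh.n_vertices, mesh.n_vertices + len(chain_pts))
        )
        mesh = Mesh(
            np.vstack([mesh.vertices, chain_pts]), mesh.faces, validate=False
        )
    else:
        chain_ids = []
    # sub1 runs ...a -> b..., so append the chain b -> a; sub2 the
    # reverse
    sub1 = BoundaryLoop(vertices=pair.sub1 + chain_ids[::-1])
    sub2 = BoundaryLoop(vertices=pair.sub2 + chain_ids)
    # loops are oriented with the surrounding triangles to the left, so
    # patch triangles are emitted flipped to keep shared-edge winding
    # opposite to the mesh
    p1_min = triangulate_boundary(sub1, mesh=mesh, flip_orientation=True)
    bridge_set = set(pair.bridge) | set(chain_ids)
    extra = [
        p1_min.vertices[list(f)]
        for f in p1_min.faces
        if any(p1_min.mesh_vertex_ids[v] in bridge_set for v in f)
    ]
    p2_min = triangulate_boundary(
        sub2, mesh=mesh, flip_orientation=True, extra_triangles=extra
    )

    p1_ref = refine_patch(p1_min, target, c=density_factor)
    p2_ref = refine_patch(p2_min, target, c=density_factor)
    p1_def, p2_def = reshape_patch(mesh, [p1_ref, p2_ref], k=k)

    lam = lam_max
    chosen = None
    while lam >= lam_floor - 1e-12:
        f1 = blend_patch(p1_ref, p1_def, lam)
        f2 = blend_patch(p2_ref, p2_def, lam)
        hit, _ = patches_intersect(f1, f2)
        if not hit:
            chosen = (f1, f2, lam)
            break
        lam = lam - tau
    if chosen is None:
        raise InterferenceError(
            "patch interference persists down to the lambda floor",
            patches=(blend_patch(p1_ref, p1_def, lam_floor),
                     blend_patch(p2_ref, p2_def, lam_floor)),
        )
    f1, f2, lam = chosen
    combined, _, maps = glue_patches(mesh, [f1, f2])
    positions = combined.vertices.copy()
    for p, l2g in zip((f1, f2), maps):
        positions[l2g[p.n_boundary :]] = p.vertices[p.n_boundary :]
    new_mesh = Mesh(positions, combined.faces, validate=False)
    return f1, f2, new_mesh, lam
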