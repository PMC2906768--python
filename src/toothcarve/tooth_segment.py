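"""Segmentation-boundary extraction and single-tooth separation.

The blending region between teeth and gingiva, re-extracted after
shape restoration, is a wide valley band.  It is thinned to a
width-one skeleton by topology-preserving peeling driven by the
*vertex complexity* CP(i): the cyclic count of membership transitions
around the ordered 1-ring of a region vertex.  Center vertices (whole
ring inside the region) and complex vertices (CP >= 4) are preserved -
removing a center would punch a spurious ring, removing a complex
vertex would disconnect the region - so only simple satellite boundary
vertices are peeled.  After pruning open branches, the remaining
closed rings are the segmentation boundary along which the mesh is cut
into single teeth plus the common gingiva/base part.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .mesh_core import Mesh, neighborhood
from .regions import VertexRegion


@dataclass
class ComplexityLabels:
    """Per-vertex complexity and the peeling classes of a region.

    ``candidates`` is the satellite set minus the preserved center and
    complex sets.
    """

    cp: dict
    satellites: frozenset
    centers: frozenset
    complexes: frozenset
    candidates: frozenset


@dataclass
class Skeleton:
    """Width-one residue of a region after peeling.

    ``rings`` holds the ordered closed vertex cycles found after
    pruning (2-regular components); ``complexes`` holds components
    where rings share vertices or edges (e.g. two tooth boundaries
    joined along one inter-dental valley line), kept as vertex sets.
    """

    mesh: Mesh
    members: frozenset
    rings: list = field(default_factory=list)
    complexes: list = field(default_factory=list)

    def graph_edges(self):
        """Mesh edges joining two skeleton members."""
        out = []
        for i in self.members:
            for j in self.mesh.vertex_neighbors(i):
                if j in self.members and i < j:
                    out.append((i, j))
        return out

    def retained_members(self):
        kept = set()
        for r in self.rings:
            kept.update(r)
        for c in self.complexes:
            kept.update(c)
        return frozenset(kept)


def _ring_membership(mesh: Mesh, i: int, members) -> list:
    return [1 if j in members else 0 for j in mesh.ordered_ring(i)]


def vertex_complexity(region: VertexRegion, i: int) -> int:
    """CP(i): cyclic sum of absolute successive differences of the
    0/1 membership pattern around the ordered 1-ring (wrap included).

    CP is even and equals twice the number of membership runs; CP >= 4
    marks a topologically critical ("complex") vertex.
    """
    if i not in region.members:
        raise ValueError(f"vertex {i} is not in the region")
    return _cp_of_pattern(_ring_membership(region.mesh, i, region.members))


def _cp_of_pattern(pattern):
    m = len(pattern)
    if m == 0:
        return 0
    return sum(
        abs(pattern[k] - pattern[(k + 1) % m]) for k in range(m)
    )


def classify(region: VertexRegion) -> ComplexityLabels:
    """Compute CP and the satellite / center / complex / candidate sets."""
    mesh = region.mesh
    members = region.members
    cp = {}
    centers = set()
    complexes = set()
    for i in members:
        ring = mesh.ordered_ring(i)
        pattern = [1 if j in members else 0 for j in ring]
        c = _cp_of_pattern(pattern)
        cp[i] = c
        if ring and all(pattern):
            centers.add(i)
        if c >= 4:
            complexes.add(i)
    satellites = set()
    for c in centers:
        for j in mesh.vertex_neighbors(c):
            if j in members:
                satellites.add(j)
    candidates = satellites - complexes - centers
    return ComplexityLabels(
        cp=cp,
        satellites=frozenset(satellites),
        centers=frozenset(centers),
        complexes=frozenset(complexes),
        candidates=frozenset(candidates),
    )


def skeletonize(region: VertexRegion) -> Skeleton:
    """Peel the region to a width-one skeleton.

    One vertex is removed per step - ascending current CP, then
    ascending index, so smooth boundary peels first and the result is
    deterministic - and the complexity of its 1-ring is updated
    locally.  A vertex is peelable exactly when CP == 2: its member
    neighbors form one contiguous arc, so removal keeps them
    connected.  Centers (CP == 0 with a full member ring) are never
    removed (that would punch a spurious ring) and complex vertices
    (CP >= 4) are never removed (that would break connectivity), so
    component count and cycle structure are preserved and the process
    runs until the shape stops changing.
    """
    mesh = region.mesh
    members = set(region.members)

    # multi-source BFS depth from the region boundary: peeling in
    # depth order keeps the surviving skeleton on the medial line of
    # the band instead of drifting toward high vertex indices
    depth = {}
    frontier = [
        i
        for i in members
        if any(j not in members for j in mesh.vertex_neighbors(i))
    ]
    for i in frontier:
        depth[i] = 0
    d = 0
    while frontier:
        nxt = []
        for i in frontier:
            for j in mesh.vertex_neighbors(i):
                if j in members and j not in depth:
                    depth[j] = d + 1
                    nxt.append(j)
        frontier = nxt
        d += 1
    for i in members:
        depth.setdefault(i, 0)

    def scramble(i):
        # deterministic index hash to avoid directional sweep bias
        return (i * 0x9E3779B1) & 0xFFFFFFFF

    cp = {}

    def recompute(i):
        cp[i] = _cp_of_pattern(
            [1 if j in members else 0 for j in mesh.ordered_ring(i)]
        )

    for i in members:
        recompute(i)

    def is_candidate(i):
        return i in members and cp[i] == 2

    version = {i: 0 for i in members}
    heap = []
    for i in members:
        if is_candidate(i):
            heapq.heappush(heap, (depth[i], cp[i], scramble(i), i, version[i]))

    while heap:
        _, c, _, i, ver = heapq.heappop(heap)
        if ver != version.get(i, -1) or not is_candidate(i):
            continue
        members.discard(i)
        affected = {j for j in mesh.vertex_neighbors(i) if j in members}
        for j in affected:
            recompute(j)
            if is_candidate(j):
                version[j] += 1
                heapq.heappush(
                    heap, (depth[j], cp[j], scramble(j), j, version[j])
                )
    return Skeleton(mesh=mesh, members=frozenset(members))


def _induced_degrees(mesh: Mesh, members):
    return {
        i: sum(1 for j in mesh.vertex_neighbors(i) if j in members)
        for i in members
    }


def prune(skeleton: Skeleton, min_ring: int = 8) -> Skeleton:
    """Delete open branches, then drop rings shorter than ``min_ring``.

    Vertices with at most one skeleton neighbor are removed
    iteratively until none remain; surviving components that are
    2-regular are ordered into closed rings, and components where
    rings share vertices (junction degree >= 3) are kept whole as ring
    complexes.  ``min_ring`` automates the removal of small redundant
    closed rings.
    """
    mesh = skeleton.mesh
    members = set(skeleton.members)
    deg = _induced_degrees(mesh, members)
    stack = [i for i, d in deg.items() if d <= 1]
    while stack:
        i = stack.pop()
        if i not in members:
            continue
        if deg[i] > 1:
            continue
        members.discard(i)
        for j in mesh.vertex_neighbors(i):
            if j in members:
                deg[j] -= 1
                if deg[j] <= 1:
                    stack.append(j)

    # connected components of the remaining skeleton graph
    remaining = set(members)
    rings = []
    complexes = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            x = frontier.pop()
            for y in mesh.vertex_neighbors(x):
                if y in remaining:
                    remaining.discard(y)
                    comp.add(y)
                    frontier.append(y)
        degs = {i: sum(1 for j in mesh.vertex_neighbors(i) if j in comp)
                for i in comp}
        if all(d == 2 for d in degs.values()):
            if len(comp) < min_ring:
                continue
            # order the cycle by walking
            start = min(comp)
            ring = [start]
            prev = None
            cur = start
            while True:
                nxt = [
                    j
                    for j in mesh.vertex_neighbors(cur)
                    if j in comp and j != prev
                ]
                nxt = nxt[0]
                if nxt == start:
                    break
                ring.append(nxt)
                prev, cur = cur, nxt
            rings.append(ring)
        else:
            if len(comp) >= min_ring:
                complexes.append(frozenset(comp))
    kept = set()
    for r in rings:
        kept.update(r)
    for c in complexes:
        kept.update(c)
    return Skeleton(
        mesh=mesh, members=frozenset(kept), rings=rings, complexes=complexes
    )


@dataclass
class SeparationResult:
    """Submeshes produced by cutting along the segmentation boundary."""

    teeth: list
    base: Mesh
    tooth_face_indices: list
    base_face_indices: np.ndarray


def _submesh(mesh: Mesh, face_idx):
    faces = mesh.faces[np.asarray(sorted(face_idx), dtype=np.int64)]
    used = np.unique(faces)
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return Mesh(mesh.vertices[used], remap[faces], validate=False)


def separate(mesh: Mesh, skeleton: Skeleton, min_part: int = 10) -> SeparationResult:
    """Cut the mesh along the skeleton rings into teeth plus base.

    Faces are flood-filled over shared edges, never crossing an edge
    whose two endpoints are joined skeleton members; cutting duplicates
    the ring vertices into each adjacent part, so teeth carry their
    cervical margin.  The largest resulting part is treated as the
    base (gingiva); every other part is one tooth.  A skeleton that
    does not separate the surface raises ``ValueError``.
    """
    barrier = set()
    for i, j in skeleton.graph_edges():
        barrier.add((i, j))
    if not barrier:
        return SeparationResult(
            teeth=[],
            base=mesh.copy(),
            tooth_face_indices=[],
            base_face_indices=np.arange(mesh.n_faces),
        )

    comp = -np.ones(mesh.n_faces, dtype=np.int64)
    n_comp = 0
    for f0 in range(mesh.n_faces):
        if comp[f0] >= 0:
            continue
        comp[f0] = n_comp
        frontier = [f0]
        while frontier:
            f = frontier.pop()
            tri = mesh.faces[f]
            for e0, e1 in ((0, 1), (1, 2), (2, 0)):
                a, b = int(tri[e0]), int(tri[e1])
                key = (min(a, b), max(a, b))
                if key in barrier:
                    continue
                for g in mesh.edge_face_indices(a, b):
                    if comp[g] < 0:
                        comp[g] = n_comp
                        frontier.append(g)
        n_comp += 1
    if n_comp < 2:
        rings = skeleton.rings or [sorted(skeleton.members)]
        raise ValueError(
            f"skeleton does not separate the surface (ring {rings[0][:8]}...)"
        )
    # fold tiny cut-debris parts (single triangles pinched off by
    # skeleton junctions) into their largest neighboring part
    sizes = np.bincount(comp, minlength=n_comp)
    for _ in range(8):
        small = [c for c in range(n_comp) if 0 < sizes[c] < min_part]
        if not small:
            break
        for c in small:
            neigh = {}
            for f in np.flatnonzero(comp == c):
                tri = mesh.faces[f]
                for e0, e1 in ((0, 1), (1, 2), (2, 0)):
                    for g in mesh.edge_face_indices(int(tri[e0]), int(tri[e1])):
                        if comp[g] != c:
                            neigh[comp[g]] = neigh.get(comp[g], 0) + 1
            if neigh:
                target = max(neigh, key=lambda x: (sizes[x], neigh[x]))
                sizes[target] += sizes[c]
                sizes[c] = 0
                comp[comp == c] = target
    labels = [c for c in range(n_comp) if sizes[c] > 0]
    relabel = {c: x for x, c in enumerate(labels)}
    comp = np.array([relabel[c] for c in comp])
    n_comp = len(labels)
    sizes = np.bincount(comp, minlength=n_comp)
    base_label = int(np.argmax(sizes))
    teeth = []
    tooth_faces = []
    for label in range(n_comp):
        if label == base_label:
            continue
        idx = np.flatnonzero(comp == label)
        teeth.append(_submesh(mesh, idx))
        tooth_faces.append(idx)
    base_idx = np.flatnonzero(comp == base_label)
    return SeparationResult(
        teeth=teeth,
        base=_submesh(mesh, base_idx),
        tooth_face_indices=tooth_faces,
        base_face_indices=base_idx,
    )
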