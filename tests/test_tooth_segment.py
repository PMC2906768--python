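"""Vertex complexity, peeling, pruning, and single-tooth separation."""

import numpy as np
import pytest

import toothcarve as tc
from toothcarve import tooth_segment as ts
from toothcarve.regions import VertexRegion


def hex_disk(rings=3):
    """Hexagonal disk of a triangulated grid: returns (mesh, layers)
    where layers[r] is the set of vertices at hex distance r."""
    n = 2 * rings + 3
    mesh = tc.make_plane_grid(n, n)
    center = (n // 2) * n + (n // 2)
    layers = [{center}]
    seen = {center}
    frontier = {center}
    for _ in range(rings):
        nxt = set()
        for i in frontier:
            nxt |= mesh.vertex_neighbors(i)
        nxt -= seen
        layers.append(nxt)
        seen |= nxt
        frontier = nxt
    return mesh, layers


def region_of(mesh, members):
    return VertexRegion(mesh=mesh, members=frozenset(int(i) for i in members))


# -- vertex complexity ------------------------------------------------


def test_cp_all_neighbors_inside_is_center(grid15):
    i = 7 * 15 + 7
    members = {i} | set(grid15.vertex_neighbors(i))
    r = region_of(grid15, members)
    assert ts.vertex_complexity(r, i) == 0
    labels = ts.classify(r)
    assert i in labels.centers


def test_cp_alternating_pattern(grid15):
    """Membership pattern 1,0,1,0,1,0 around the ring gives CP = 6."""
    i = 7 * 15 + 7
    ring = grid15.ordered_ring(i)
    members = {i} | {v for k, v in enumerate(ring) if k % 2 == 0}
    r = region_of(grid15, members)
    assert ts.vertex_complexity(r, i) == 6
    assert i in ts.classify(r).complexes


def test_cp_contiguous_arc(grid15):
    """One contiguous arc of members (1,1,1,0,0,0) gives CP = 2."""
    i = 7 * 15 + 7
    ring = grid15.ordered_ring(i)
    members = {i} | set(ring[:3])
    r = region_of(grid15, members)
    assert ts.vertex_complexity(r, i) == 2
    assert i not in ts.classify(r).complexes


def test_cp_requires_membership(grid15):
    r = region_of(grid15, {0})
    with pytest.raises(ValueError):
        ts.vertex_complexity(r, 5)


def test_cp_is_even_everywhere(grid15):
    rng = np.random.default_rng(4)
    members = set(
        np.flatnonzero(rng.random(grid15.n_vertices) < 0.5).tolist()
    )
    r = region_of(grid15, members)
    for i in list(members)[:50]:
        assert ts.vertex_complexity(r, i) % 2 == 0


# -- classify ---------------------------------------------------------


def test_classify_solid_disk():
    """On a solid hex disk the deep interior vertices are centers, the
    members adjacent to centers are satellites, and candidates are the
    satellites that are neither centers nor complex."""
    mesh, layers = hex_disk(3)
    members = set().union(*layers)
    r = region_of(mesh, members)
    labels = ts.classify(r)
    assert layers[0] <= labels.centers
    assert layers[1] <= labels.centers  # their rings are inside too
    assert labels.candidates <= labels.satellites
    assert not labels.candidates & labels.centers
    assert not labels.candidates & labels.complexes
    assert labels.candidates  # the rim provides candidates


def test_classify_width_one_ring_no_candidates(cylinder_band_mesh):
    mesh, vid, nt, nz = cylinder_band_mesh
    ring = {vid(i, 10) for i in range(nt)}
    labels = ts.classify(region_of(mesh, ring))
    assert not labels.centers
    assert labels.candidates == frozenset()


def test_classify_empty_region(grid15):
    labels = ts.classify(region_of(grid15, set()))
    assert not (labels.centers | labels.satellites | labels.candidates)


# -- skeletonize ------------------------------------------------------


def test_skeletonize_width_one_ring_fixpoint(cylinder_band_mesh):
    mesh, vid, nt, nz = cylinder_band_mesh
    ring = frozenset(vid(i, 10) for i in range(nt))
    sk = ts.skeletonize(region_of(mesh, ring))
    assert sk.members == ring


def test_skeletonize_annulus_band_single_ring(cylinder_band_mesh):
    """A 3-vertex-wide band around the cylinder peels to one closed
    ring winding once around the axis."""
    mesh, vid, nt, nz = cylinder_band_mesh
    band = {vid(i, j) for i in range(nt) for j in (9, 10, 11)}
    sk = ts.skeletonize(region_of(mesh, band))
    pr = ts.prune(sk, min_ring=8)
    assert len(pr.rings) == 1 and not pr.complexes
    ring = pr.rings[0]
    ang = np.unwrap(
        [np.arctan2(mesh.vertices[v][1], mesh.vertices[v][0]) for v in ring]
        + [np.arctan2(mesh.vertices[ring[0]][1], mesh.vertices[ring[0]][0])]
    )
    assert abs(abs(ang[-1] - ang[0]) / (2 * np.pi) - 1.0) < 1e-9
    # prune output is 2-regular
    rs = set(ring)
    for v in ring:
        assert sum(1 for j in mesh.vertex_neighbors(v) if j in rs) == 2


def test_skeletonize_preserves_component_count(cylinder_band_mesh):
    mesh, vid, nt, nz = cylinder_band_mesh
    band1 = {vid(i, j) for i in range(nt) for j in (4, 5)}
    band2 = {vid(i, j) for i in range(nt) for j in (14, 15)}
    r = region_of(mesh, band1 | band2)
    assert len(r.components()) == 2
    sk = ts.skeletonize(r)
    assert len(region_of(mesh, sk.members).components()) == 2


def test_skeletonize_solid_disk_reaches_fixpoint():
    mesh, layers = hex_disk(3)
    members = set().union(*layers)
    sk = ts.skeletonize(region_of(mesh, members))
    # fixpoint: no remaining vertex is peelable (CP == 2)
    r = region_of(mesh, sk.members)
    for i in sk.members:
        assert ts.vertex_complexity(r, i) != 2
    assert len(region_of(mesh, sk.members).components()) <= 1


# -- prune ------------------------------------------------------------


def test_prune_ring_with_tail():
    """Iterative endpoint deletion removes an attached open branch and
    leaves the closed ring (hand-traceable 12+2 vertex fixture)."""
    n = 12
    th = 2 * np.pi * np.arange(n) / n
    pts = [[np.cos(t), np.sin(t), 0.0] for t in th] + [[0.0, 0.0, 0.0]]
    faces = [[i, (i + 1) % n, n] for i in range(n)]
    # a thin two-triangle strip hanging off ring vertex 0: the tail
    # chain 0 - t1 - t3 attaches through single edges
    pts += [[1.4, 0.0, 0.0], [1.35, 0.35, 0.0], [1.8, 0.15, 0.0]]
    t1, t2, t3 = n + 1, n + 2, n + 3
    faces += [[0, t2, t1], [t1, t2, t3]]
    mesh = tc.Mesh(np.array(pts), np.array(faces), validate=False)
    ring = set(range(n))
    sk = ts.Skeleton(mesh=mesh, members=frozenset(ring | {t1, t3}))
    pr = ts.prune(sk, min_ring=8)
    assert pr.retained_members() == frozenset(ring)
    assert len(pr.rings) == 1


def test_prune_open_path_vanishes(grid15):
    path = {7 * 15 + j for j in range(3, 12)}
    sk = ts.Skeleton(mesh=grid15, members=frozenset(path))
    pr = ts.prune(sk, min_ring=3)
    assert pr.retained_members() == frozenset()


def test_prune_drops_short_rings(cylinder_band_mesh):
    """A triangle-sized ring below min_ring is dropped; the long ring
    survives."""
    mesh, vid, nt, nz = cylinder_band_mesh
    big = {vid(i, 10) for i in range(nt)}
    f = mesh.faces[0]
    small = {int(v) for v in f}
    sk = ts.Skeleton(mesh=mesh, members=frozenset(big | small))
    pr = ts.prune(sk, min_ring=10)
    assert pr.retained_members() == frozenset(big)


# -- separate ---------------------------------------------------------


def test_separate_no_rings_identity(grid15):
    sk = ts.Skeleton(mesh=grid15, members=frozenset())
    sep = ts.separate(grid15, sk)
    assert sep.teeth == []
    assert sep.base.n_faces == grid15.n_faces


def test_separate_cylinder_band(cylinder_band_mesh):
    mesh, vid, nt, nz = cylinder_band_mesh
    band = {vid(i, j) for i in range(nt) for j in (9, 10, 11)}
    pr = ts.prune(ts.skeletonize(region_of(mesh, band)), min_ring=8)
    sep = ts.separate(mesh, pr)
    assert len(sep.teeth) == 1
    # cut contract: the tooth's new boundary loop has the ring's length
    from toothcarve.mesh_core import boundary_loops

    ring_len = len(pr.rings[0])
    loops = sorted(len(l) for l in boundary_loops(sep.teeth[0]))
    assert ring_len in loops


def test_separate_nonseparating_ring_errors(cylinder_band_mesh):
    """A meridian (non-separating on an open cylinder wall) path that
    does not close cannot split the surface."""
    mesh, vid, nt, nz = cylinder_band_mesh
    path = frozenset(vid(0, j) for j in range(nz))
    sk = ts.Skeleton(mesh=mesh, members=path, rings=[sorted(path)])
    with pytest.raises(ValueError):
        ts.separate(mesh, sk)


@pytest.mark.parametrize("n_cusps", [2, 4])
def test_phantom_n_cusps_yield_n_teeth(n_cusps):
    """An unfused n-cusp phantom segments into exactly n teeth."""
    spec = tc.PhantomSpec(n_cusps=n_cusps, resolution=0.45)
    mesh, gt = tc.make_dental_phantom(spec)
    from toothcarve import curvature as cv, regions as rg

    f = cv.curvature_field(mesh, smooth_passes=1)
    region = rg.threshold_region(mesh, f, t=-0.25)
    region = rg.apply_morphology(region, [("close", 1)])
    region = rg.remove_small_components(region, 30)
    pr = ts.prune(ts.skeletonize(region), min_ring=8)
    sep = ts.separate(mesh, pr)
    assert len(sep.teeth) == n_cusps
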