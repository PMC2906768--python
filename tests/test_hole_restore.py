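"""Occlusal plane, saddle bridging, weight-rule triangulation,
refinement, k-harmonic fairing, blending, and interference checks."""

import math

import numpy as np
import pytest

import toothcarve as tc
from toothcarve import hole_restore as hr
from toothcarve.hole_restore import (
    Patch,
    TriangulationState,
    blend_patch,
    bridge_hole,
    fit_occlusal_plane,
    laplacian_matrix,
    patches_intersect,
    refine_patch,
    reshape_patch,
    restore_hole,
    tri_tri_intersect,
    triangulate_boundary,
)
from toothcarve.mesh_core import BoundaryLoop, boundary_loops


# -- occlusal plane ---------------------------------------------------


def test_plane_through_coplanar_points():
    pts = np.array([[0, 0, 1], [1, 0, 1], [0, 1, 1], [1, 1, 1.0]])
    plane = fit_occlusal_plane(pts)
    assert np.allclose(np.abs(plane.normal), [0, 0, 1])
    assert plane.distance(pts).max() < 1e-12


def test_plane_symmetric_residuals():
    eps = 0.05
    pts = np.array(
        [[0, 0, eps], [0, 1, -eps], [1, 0, -eps], [1, 1, eps]]
    )
    plane = fit_occlusal_plane(pts)
    assert abs(plane.normal @ [0, 0, 1]) > 0.999
    assert abs(plane.offset) < 1e-9


def test_plane_matches_svd_oracle():
    """Total least squares: the normal is the smallest right singular
    vector of the centered points (independent SVD evaluation)."""
    rng = np.random.default_rng(5)
    for _ in range(5):
        pts = rng.normal(size=(4, 3))
        plane = fit_occlusal_plane(pts, up_hint=(0, 0, 1))
        c = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(c)
        n = vt[2] if vt[2] @ [0, 0, 1] >= 0 else -vt[2]
        assert np.allclose(np.abs(plane.normal @ n), 1.0, atol=1e-9)
        # residual optimality: no nearby plane does better
        def sq(nrm, off):
            return np.sum((pts @ nrm - off) ** 2)
        base = sq(plane.normal, plane.offset)
        for _ in range(20):
            d = rng.normal(scale=1e-3, size=3)
            nrm = plane.normal + d
            nrm = nrm / np.linalg.norm(nrm)
            off = float(np.mean(pts @ nrm))
            assert base <= sq(nrm, off) + 1e-12


def test_plane_collinear_errors():
    pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0.0]])
    with pytest.raises(ValueError):
        fit_occlusal_plane(pts)


# -- bridging ---------------------------------------------------------


def fan_disk(loop_pts):
    """Disk mesh whose boundary loop is exactly the given polygon."""
    n = len(loop_pts)
    centroid = np.mean(loop_pts, axis=0)
    verts = np.vstack([loop_pts, centroid])
    faces = [[i, (i + 1) % n, n] for i in range(n)]
    return tc.Mesh(verts, np.asarray(faces), validate=False)


def test_bridge_saddle_analytic_maxima():
    """Loop sampled from z = xy on the unit circle, reference plane far
    below: the bridge endpoints are the two highest loop points, at
    theta = 45 and 225 degrees."""
    n = 40
    th = 2 * np.pi * np.arange(n) / n
    pts = np.column_stack(
        [np.cos(th), np.sin(th), np.cos(th) * np.sin(th)]
    )
    mesh = fan_disk(pts)
    loop = BoundaryLoop(vertices=list(range(n)))
    plane = fit_occlusal_plane(
        np.array([[0, 0, -10], [1, 0, -10], [0, 1, -10], [1, 1, -10.0]])
    )
    pair = bridge_hole(mesh, loop, plane)
    got = {pair.bridge[0], pair.bridge[1]}
    expect = {n // 8, n // 2 + n // 8}  # theta = 45, 225 degrees
    assert got == expect
    assert len(pair.sub1) + len(pair.sub2) == n + 2
    # symmetric saddle: mirror subloops
    assert abs(len(pair.sub1) - len(pair.sub2)) <= 1


def test_bridge_counting_invariant(fused_phantom):
    mesh, gt = fused_phantom
    region = tc.VertexRegion(mesh=mesh, members=gt["fusion_sets"][0])
    cut, loops = tc.cut_hole(mesh, region)
    plane = fit_occlusal_plane(gt["occlusal_points"])
    pair = bridge_hole(cut, loops[0], plane)
    assert len(pair.sub1) + len(pair.sub2) == len(loops[0]) + 2


def test_bridge_no_saddle_errors():
    n = 12
    th = 2 * np.pi * np.arange(n) / n
    pts = np.column_stack([np.cos(th), np.sin(th), np.zeros(n)])
    mesh = fan_disk(pts)
    plane = fit_occlusal_plane(
        np.array([[0, 0, -1], [1, 0, -1], [0, 1, -1], [1, 1, -1.0]])
    )
    with pytest.raises(ValueError):
        bridge_hole(mesh, BoundaryLoop(vertices=list(range(n))), plane)


# -- triangle weight --------------------------------------------------


def equilateral_triple_loop():
    """A hexagon whose first three vertices form unit edges."""
    pts = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0],
            [0.5, math.sqrt(3) / 2, 0.0],
            [0.0, 2.0, 0.0],
            [-1.5, 1.0, 0.0],
            [-1.0, -1.0, 0.0],
        ]
    )
    return pts


def test_weight_perimeter_branch():
    """Plain interior case with unit edges: weight is minus the
    perimeter, -3."""
    pts = equilateral_triple_loop()
    st = TriangulationState(pts, radius=5.0)
    # apex 1 has prev 0 and next 2: edges (0,1), (1,2), (0,2) all unit
    assert st.weight(1) == pytest.approx(-3.0)


def test_weight_l_bigger_branch():
    pts = equilateral_triple_loop()
    st = TriangulationState(pts, radius=5.0)
    st.neiT[1] = 9
    assert st.weight(1) == pytest.approx((9 / 8) * 5.0)


def test_weight_l_less_branch():
    pts = equilateral_triple_loop()
    st = TriangulationState(pts, radius=5.0)
    st.A[1] = 0.5 * math.pi  # sharp open corner, below alpha*pi
    assert st.weight(1) == pytest.approx(-(math.pi / (0.5 * math.pi)) * 5.0)


def test_weight_projection_violation_is_minus_inf():
    """A spoke of the apex crossing the candidate's far edge in the
    tangent-plane projection forces weight -inf."""
    pts = equilateral_triple_loop()
    st = TriangulationState(pts, radius=5.0)
    # spoke from apex 1 to a point far beyond the far edge (0, 2)
    st.adj[1].append(np.array([-0.5, 2.0, 0.0]))
    st.nsum[1] = np.array([0.0, 0.0, 1.0])
    assert st.weight(1) == hr.NEG_INF


# -- spanning triangulation -------------------------------------------


def test_triangle_loop_single_face():
    p = triangulate_boundary(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.0]]))
    assert len(p.faces) == 1
    assert p.n_boundary == 3


@pytest.mark.parametrize("n,seed", [(50, 0), (120, 1), (241, 1)])
def test_spanning_triangulation_counts(n, seed):
    """A simple closed loop of n vertices spans exactly n - 2 triangles
    over exactly the n boundary vertices."""
    loop = tc.phantoms.make_jagged_loop(n, seed=seed)
    p = triangulate_boundary(loop)
    assert len(p.faces) == n - 2
    assert len(p.vertices) == n
    assert set(np.unique(p.faces)) == set(range(n))
    # every boundary edge used exactly once; Euler for a disk
    from collections import Counter

    cnt = Counter()
    for f in p.faces:
        for u, v in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            cnt[(min(u, v), max(u, v))] += 1
    boundary_edges = [
        e for e, c in cnt.items() if c == 1
    ]
    assert len(boundary_edges) == n


def test_planar_convex_polygon_no_overlap():
    """A planar convex 10-gon triangulates into 8 one-sided triangles
    with pairwise disjoint interiors (shapely overlap oracle)."""
    from shapely.geometry import Polygon

    n = 10
    th = 2 * np.pi * np.arange(n) / n
    loop = np.column_stack([np.cos(th), np.sin(th), np.zeros(n)])
    p = triangulate_boundary(loop)
    assert len(p.faces) == 8
    normals = [
        np.cross(
            p.vertices[f[1]] - p.vertices[f[0]],
            p.vertices[f[2]] - p.vertices[f[0]],
        )[2]
        for f in p.faces
    ]
    assert all(z > 0 for z in normals) or all(z < 0 for z in normals)
    polys = [Polygon(p.vertices[f][:, :2]) for f in p.faces]
    for i in range(len(polys)):
        for j in range(i + 1, len(polys)):
            assert polys[i].intersection(polys[j]).area < 1e-12


def reference_triangulate(positions, radius, alpha=1.2):
    """Quadratic-time rescan reference: at each step the full working
    boundary state (angle sums, triangle counts, incident edges) is
    rebuilt from scratch from the accumulated patch, every remaining
    triple is weighted, and the maximum (lowest index on ties) is
    clipped."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    B = list(range(n))
    tris = []
    while len(B) >= 3:
        state = TriangulationState(
            positions, radius=radius, alpha=alpha, boundary=B
        )
        # rebuild bookkeeping from the accumulated triangles
        for (a, b, c) in tris:
            pa, pb, pc = positions[a], positions[b], positions[c]
            for (v, q, r) in ((a, pb, pc), (b, pa, pc), (c, pa, pb)):
                state.A[v] += hr._angle(positions[v], q, r)
                state.neiT[v] += 1
                state.nsum[v] += np.cross(pb - pa, pc - pa)
                state.adj[v].extend([q, r])
                state.opp[v].append((q, r))
        best = None
        for i in B:
            w = state.weight(i)
            if best is None or w > best[0] or (w == best[0] and i < best[1]):
                best = (w, i)
        w, i = best
        if w == hr.NEG_INF:
            i = min(B, key=lambda x: (state.perimeter(x), x))
        pos_i = B.index(i)
        j = B[pos_i - 1]
        k = B[(pos_i + 1) % len(B)]
        tris.append((j, i, k))
        B.remove(i)
    return tris


@pytest.mark.parametrize("seed", range(6))
def test_queue_matches_quadratic_rescan(seed):
    """The O(N log N) weight-queue triangulation is triangle-for-
    triangle identical to the quadratic rescan reference."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 61))
    loop = tc.phantoms.make_jagged_loop(n, seed=seed + 100)
    lo = loop.min(axis=0)
    hi = loop.max(axis=0)
    radius = 0.5 * float(np.linalg.norm(hi - lo))
    fast = triangulate_boundary(loop, radius=radius)
    ref = reference_triangulate(loop, radius=radius)
    assert [tuple(f) for f in fast.faces] == ref


# -- refinement -------------------------------------------------------


def one_triangle_patch(L=3.0):
    verts = np.array(
        [[0, 0, 0], [L, 0, 0], [L / 2, L * math.sqrt(3) / 2, 0.0]]
    )
    return Patch(
        vertices=verts, faces=np.array([[0, 1, 2]]), n_boundary=3
    )


def test_refine_noop_when_dense():
    p = one_triangle_patch(L=1.0)
    out = refine_patch(p, target_edge_length=5.0)
    assert len(out.faces) == 1
    assert np.array_equal(out.vertices, p.vertices)


def test_refine_single_centroid_split():
    """One 1-to-3 split: the big triangle becomes three triangles
    sharing the centroid vertex."""
    L = 3.0
    p = one_triangle_patch(L)
    out = refine_patch(p, target_edge_length=0.55 * L, c=1.5)
    assert len(out.faces) == 3
    centroid = p.vertices.mean(axis=0)
    assert np.allclose(out.vertices[3], centroid)
    assert all(3 in f for f in out.faces)


def test_refine_density_matches_surround(sphere3):
    """After refinement the patch mean edge length is within a factor
    1.5 of the surrounding mesh's."""
    cap = [i for i in range(sphere3.n_vertices) if sphere3.vertices[i, 2] > 0.75]
    cut, loops = tc.cut_hole(
        sphere3, tc.VertexRegion(mesh=sphere3, members=frozenset(cap))
    )
    p = triangulate_boundary(loops[0], mesh=cut, flip_orientation=True)
    target = hr.surrounding_edge_length(cut, loops[0].vertices)
    out = refine_patch(p, target, c=1.5)
    edges = set()
    for f in out.faces:
        for u, v in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            edges.add((min(u, v), max(u, v)))
    lens = [
        np.linalg.norm(out.vertices[u] - out.vertices[v]) for u, v in edges
    ]
    ratio = np.mean(lens) / target
    assert 1 / 1.5 <= ratio <= 1.5


# -- k-harmonic fairing -----------------------------------------------


def planar_hole_setup():
    g = tc.make_plane_grid(15, 15)
    hole = {i * 15 + j for i in range(5, 10) for j in range(5, 10)}
    cut, loops = tc.cut_hole(
        g, tc.VertexRegion(mesh=g, members=frozenset(hole))
    )
    loop = min(loops, key=len)
    p = triangulate_boundary(loop, mesh=cut, flip_orientation=True)
    pr = refine_patch(p, cut.mean_edge_length())
    return cut, pr


def test_cotangent_laplacian_linear_precision(grid15):
    """The discrete Laplacian of the coordinate functions vanishes at
    interior vertices of a planar mesh (harmonicity of linear maps)."""
    L = laplacian_matrix(grid15)
    vals = L @ grid15.vertices
    interior = [
        i
        for i in range(grid15.n_vertices)
        if not grid15.is_boundary_vertex(i)
    ]
    assert np.abs(vals[interior]).max() < 1e-9


def test_reshape_k1_planar_hole():
    cut, pr = planar_hole_setup()
    pd = reshape_patch(cut, pr, k=1)
    assert np.abs(pd.vertices[:, 2]).max() < 1e-8


def test_reshape_k2_spherical_cap(sphere3):
    """Thin-plate fill of a spherical cap stays within 0.02 R of the
    analytic sphere (RMS over interior vertices)."""
    cap = [i for i in range(sphere3.n_vertices) if sphere3.vertices[i, 2] > 0.75]
    cut, loops = tc.cut_hole(
        sphere3, tc.VertexRegion(mesh=sphere3, members=frozenset(cap))
    )
    p = triangulate_boundary(loops[0], mesh=cut, flip_orientation=True)
    pr = refine_patch(p, cut.mean_edge_length())
    pd = reshape_patch(cut, pr, k=2)
    interior = pd.vertices[pd.n_boundary :]
    d = np.abs(np.linalg.norm(interior, axis=1) - 1.0)
    assert math.sqrt(np.mean(d**2)) < 0.02


def test_reshape_reduces_thin_plate_energy():
    cut, pr = planar_hole_setup()
    # bend the raw patch out of plane so there is energy to remove
    bent = pr.copy()
    rng = np.random.default_rng(0)
    bent.vertices[bent.n_boundary :, 2] += rng.normal(
        0.2, 0.1, size=len(bent.vertices) - bent.n_boundary
    )
    pd = reshape_patch(cut, bent, k=2)

    def energy(patch):
        combined, interiors, _ = hr.glue_patches(cut, [patch])
        L = laplacian_matrix(combined)
        lx = L @ combined.vertices
        return float(np.sum(lx[interiors[0]] ** 2))

    assert energy(pd) < energy(bent)


def test_reshape_invalid_order(sphere3):
    cut, pr = planar_hole_setup()
    for k in (0, 4):
        with pytest.raises(ValueError):
            reshape_patch(cut, pr, k=k)


def test_reshape_boundary_fixed():
    cut, pr = planar_hole_setup()
    pd = reshape_patch(cut, pr, k=2)
    nb = pr.n_boundary
    assert np.allclose(pd.vertices[:nb], pr.vertices[:nb])


# -- blending ---------------------------------------------------------


def test_blend_endpoints_and_midpoint():
    cut, pr = planar_hole_setup()
    pd = reshape_patch(cut, pr, k=2)
    assert np.array_equal(blend_patch(pr, pd, 1.0).vertices, pd.vertices)
    near0 = blend_patch(pr, pd, 1e-12)
    assert np.abs(near0.vertices - pr.vertices).max() < 1e-9
    mid = blend_patch(pr, pd, 0.5)
    assert np.allclose(mid.vertices, 0.5 * (pr.vertices + pd.vertices))
    for lam in (0.0, 1.5, -0.1):
        with pytest.raises(ValueError):
            blend_patch(pr, pd, lam)


# -- triangle-triangle intersection -----------------------------------


def seg_tri_clip_oracle(t1, t2):
    """Brute-force oracle: any edge of one triangle pierces the other."""

    def seg_hits_tri(p0, p1, tri):
        n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
        nn = np.linalg.norm(n)
        if nn < 1e-300:
            return False
        d0 = np.dot(p0 - tri[0], n)
        d1 = np.dot(p1 - tri[0], n)
        if d0 * d1 > 0:
            return False
        if abs(d0 - d1) < 1e-300:
            return False
        t = d0 / (d0 - d1)
        q = p0 + t * (p1 - p0)
        # barycentric containment
        v0 = tri[1] - tri[0]
        v1 = tri[2] - tri[0]
        v2 = q - tri[0]
        d00, d01, d11 = v0 @ v0, v0 @ v1, v1 @ v1
        d20, d21 = v2 @ v0, v2 @ v1
        den = d00 * d11 - d01 * d01
        if abs(den) < 1e-300:
            return False
        a = (d11 * d20 - d01 * d21) / den
        b = (d00 * d21 - d01 * d20) / den
        return a >= -1e-12 and b >= -1e-12 and a + b <= 1 + 1e-12

    for i in range(3):
        if seg_hits_tri(t1[i], t1[(i + 1) % 3], t2):
            return True
        if seg_hits_tri(t2[i], t2[(i + 1) % 3], t1):
            return True
    return False


def test_tri_tri_simple_cases():
    a = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.0]])
    b = a + [0, 0, 1.0]
    assert not tri_tri_intersect(a, b)
    c = np.array([[0.2, 0.2, -0.5], [0.2, 0.2, 0.5], [0.8, 0.8, 0.0]])
    assert tri_tri_intersect(a, c)


def test_tri_tri_matches_clipping_oracle():
    """Randomized pairs agree with the exhaustive segment-clipping
    oracle."""
    rng = np.random.default_rng(11)
    mismatch = 0
    for _ in range(1000):
        t1 = rng.uniform(-1, 1, size=(3, 3))
        t2 = rng.uniform(-1, 1, size=(3, 3))
        if tri_tri_intersect(t1, t2) != seg_tri_clip_oracle(t1, t2):
            mismatch += 1
    assert mismatch == 0


def test_patches_intersect_excludes_shared_vertices():
    a = Patch(
        vertices=np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.0]]),
        faces=np.array([[0, 1, 2]]),
        n_boundary=3,
    )
    b = Patch(
        vertices=np.array([[0, 0, 0], [-1, 0, 0], [0, -1, 0.0]]),
        faces=np.array([[0, 1, 2]]),
        n_boundary=3,
    )
    hit, _ = patches_intersect(a, b)
    assert not hit


# -- restoration pipeline ---------------------------------------------


def test_restore_hole_full(fused_phantom):
    """Saddle hole in the fused two-cusp phantom: the restoration is
    watertight, genus-preserving, keeps lambda in [0.8, 1], and pins
    the patch boundaries to the original subloop positions."""
    mesh, gt = fused_phantom
    region = tc.VertexRegion(mesh=mesh, members=gt["fusion_sets"][0])
    cut, loops = tc.cut_hole(mesh, region)
    plane = fit_occlusal_plane(gt["occlusal_points"])
    loop = loops[0]
    loop_pos = {v: cut.vertices[v].copy() for v in loop.vertices}
    p1, p2, new_mesh, lam = restore_hole(cut, loop, plane)
    assert 0.8 <= lam <= 1.0
    assert new_mesh.is_watertight()
    # genus unchanged: Euler characteristic of the referenced surface
    used = np.unique(new_mesh.faces)
    sub = tc.Mesh(
        new_mesh.vertices[used],
        np.searchsorted(used, new_mesh.faces),
        validate=False,
    )
    assert sub.euler_characteristic() == 2
    # no interference at the accepted lambda
    hit, _ = patches_intersect(p1, p2)
    assert not hit
    # boundary vertices coincide with the original loop positions
    for p in (p1, p2):
        for local, vid in enumerate(p.mesh_vertex_ids):
            if int(vid) in loop_pos:
                assert np.allclose(
                    p.vertices[local], loop_pos[int(vid)], atol=1e-12
                )


def test_restore_isolated_hole_keeps_lambda_one(fused_phantom):
    mesh, gt = fused_phantom
    region = tc.VertexRegion(mesh=mesh, members=gt["fusion_sets"][0])
    cut, loops = tc.cut_hole(mesh, region)
    plane = fit_occlusal_plane(gt["occlusal_points"])
    _, _, _, lam = restore_hole(cut, loops[0], plane)
    assert lam == 1.0  # nothing else nearby to interfere with


def test_restore_validates_tau(fused_phantom):
    mesh, gt = fused_phantom
    region = tc.VertexRegion(mesh=mesh, members=gt["fusion_sets"][0])
    cut, loops = tc.cut_hole(mesh, region)
    plane = fit_occlusal_plane(gt["occlusal_points"])
    with pytest.raises(ValueError):
        restore_hole(cut, loops[0], plane, tau=0.02)
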