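"""Synthetic fixtures: analytic tori, grids, spheres, dental phantoms.

Scanner-acquired dental casts are not redistributable, so every stage
of the toolkit is exercised on procedurally generated stand-ins:

* analytic torus meshes with closed-form curvature oracles and
  optional Gaussian vertex noise (for estimator accuracy/robustness);
* flat triangulated grids and icospheres (planar/spherical oracles);
* a multi-cusp **dental phantom**: a heightfield of cusp-like Gaussian
  bumps over a flat gum plane, closed into a watertight slab.  Fused
  pairs of cusps merge without a gap, reproducing the valley-shaped
  fusion regions between adjoining teeth; the phantom returns
  ground-truth cusp / fusion / blending vertex sets for end-to-end
  checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .curvature import area_weighted_normal
from .mesh_core import Mesh, BoundaryLoop, boundary_loops
from .regions import VertexRegion


# ---------------------------------------------------------------------
# torus with analytic curvature oracle
# ---------------------------------------------------------------------


@dataclass
class TorusSpec:
    """Torus x = ((R + r cos v) cos u, (R + r cos v) sin u, r sin v)."""

    R: float = 2.0
    r: float = 1.0
    n_u: int = 100
    n_v: int = 50
    h: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.R > self.r > 0:
            raise ValueError("need R > r > 0")
        if self.n_u < 3 or self.n_v < 3:
            raise ValueError("need n_u, n_v >= 3")


def torus_analytic_curvatures(spec: TorusSpec, v_angles):
    """Closed-form (kH, kG, kmin) at tube angle v.

    Principal curvatures of the torus with respect to the outward
    normal: k1 = 1/r around the tube, k2 = cos v / (R + r cos v)
    around the wheel.
    """
    k1 = np.full_like(v_angles, 1.0 / spec.r, dtype=float)
    k2 = np.cos(v_angles) / (spec.R + spec.r * np.cos(v_angles))
    kH = (k1 + k2) / 2.0
    kG = k1 * k2
    kmin = np.minimum(k1, k2)
    return kH, kG, kmin


def make_torus(spec: TorusSpec):
    """Sampled torus mesh plus per-vertex analytic curvature oracle.

    Returns ``(mesh, oracle)`` where oracle has keys ``kH``, ``kG``,
    ``kmin``, ``u``, ``v``.  Noise level ``h`` displaces vertices along
    the analytic normal by a zero-mean Gaussian with standard
    deviation h x (mean edge length).
    """
    nu, nv = spec.n_u, spec.n_v
    u = 2 * np.pi * np.arange(nu) / nu
    v = 2 * np.pi * np.arange(nv) / nv
    uu, vv = np.meshgrid(u, v, indexing="ij")
    x = (spec.R + spec.r * np.cos(vv)) * np.cos(uu)
    y = (spec.R + spec.r * np.cos(vv)) * np.sin(uu)
    z = spec.r * np.sin(vv)
    verts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])

    def vid(i, j):
        return (i % nu) * nv + (j % nv)

    faces = []
    for i in range(nu):
        for j in range(nv):
            a = vid(i, j)
            b = vid(i + 1, j)
            c = vid(i + 1, j + 1)
            d = vid(i, j + 1)
            faces.append((a, b, c))
            faces.append((a, c, d))
    mesh = Mesh(verts, np.asarray(faces, dtype=np.int64))
    # make sure winding points outward
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    if tm.volume < 0:
        mesh = Mesh(verts, np.asarray(faces)[:, ::-1].copy())
    kH, kG, kmin = torus_analytic_curvatures(spec, vv.ravel())
    oracle = {"kH": kH, "kG": kG, "kmin": kmin, "u": uu.ravel(), "v": vv.ravel()}
    if spec.h > 0:
        # analytic outward normal direction at (u, v)
        n = np.column_stack(
            [
                np.cos(vv.ravel()) * np.cos(uu.ravel()),
                np.cos(vv.ravel()) * np.sin(uu.ravel()),
                np.sin(vv.ravel()),
            ]
        )
        sigma = spec.h * mesh.mean_edge_length()
        rng = np.random.default_rng(spec.seed)
        disp = rng.normal(0.0, sigma, size=len(verts))
        mesh = Mesh(mesh.vertices + disp[:, None] * n, mesh.faces, validate=False)
    return mesh, oracle


def add_noise(mesh: Mesh, h: float, seed: int = 0) -> Mesh:
    """Displace each vertex along its outward normal by N(0, sigma)
    with sigma = h x (mean edge length).  Reproducible for a seed."""
    if h < 0:
        raise ValueError("noise level must be >= 0")
    if h == 0:
        return mesh.copy()
    sigma = h * mesh.mean_edge_length()
    rng = np.random.default_rng(seed)
    disp = rng.normal(0.0, sigma, size=mesh.n_vertices)
    normals = np.array(
        [area_weighted_normal(mesh, i) for i in range(mesh.n_vertices)]
    )
    return Mesh(mesh.vertices + disp[:, None] * normals, mesh.faces, validate=False)


# ---------------------------------------------------------------------
# simple oracles: grid and sphere
# ---------------------------------------------------------------------


def make_plane_grid(nx: int, ny: int, dx: float = 1.0, heightfn=None) -> Mesh:
    """Triangulated rectangular grid (diagonal split: interior vertices
    have six neighbors).  ``heightfn(x, y)`` lifts it to a heightfield."""
    xs = np.arange(nx) * dx
    ys = np.arange(ny) * dx
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    zz = np.zeros_like(xx) if heightfn is None else heightfn(xx, yy)
    verts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    def vid(i, j):
        return i * ny + j

    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a, b = vid(i, j), vid(i + 1, j)
            c, d = vid(i + 1, j + 1), vid(i, j + 1)
            faces.append((a, b, c))
            faces.append((a, c, d))
    return Mesh(verts, np.asarray(faces, dtype=np.int64))


def make_sphere(subdivisions: int = 3, radius: float = 1.0) -> Mesh:
    """Icosphere with outward-wound faces."""
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return Mesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def make_jagged_loop(
    n: int, radius: float = 10.0, amp: float = 1.5, waves: int = 7, seed: int = 0
):
    """Simple closed non-planar polygon: a circle with sinusoidal
    height modulation and a smooth seeded radial wobble (a synthetic
    stand-in for a scanned hole boundary)."""
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * np.pi, size=3)
    theta = 2 * np.pi * np.arange(n) / n
    rad = radius * (1.0 + 0.08 * np.sin(3 * theta + phase[1]))
    z = amp * np.sin(waves * theta + phase[0])
    return np.column_stack([rad * np.cos(theta), rad * np.sin(theta), z])


# ---------------------------------------------------------------------
# dental phantom
# ---------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Procedural multi-cusp dental phantom.

    Cusps are Gaussian bumps of height ``cusp_height`` and width
    ``cusp_width`` placed along a row with the given spacings; gaps
    listed in ``fused`` use ``fused_spacing`` (close enough that the
    bumps merge with no gap, emulating a fusion region), other gaps
    use ``spacing`` and get a shallow groove of depth ``groove_depth``.
    Units are mm at dental-cast scale; defaults give a clear
    sign-separated minimum-curvature field at the default resolution.
    """

    n_cusps: int = 2
    cusp_height: float = 5.0
    cusp_width: float = 2.4
    spacing: float = 7.0
    fused_spacing: float = 3.4
    fused: tuple = ()
    groove_depth: float = 0.6
    margin: float = 5.5
    resolution: float = 0.35
    base_depth: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cusps < 1:
            raise ValueError("need at least one cusp")
        for g in self.fused:
            if not 0 <= g < self.n_cusps - 1:
                raise ValueError(f"fused gap {g} out of range")


def _phantom_layout(spec: PhantomSpec):
    xs = [0.0]
    for g in range(spec.n_cusps - 1):
        step = spec.fused_spacing if g in spec.fused else spec.spacing
        xs.append(xs[-1] + step)
    xs = np.asarray(xs)
    xs = xs - xs.mean()
    return xs


def make_dental_phantom(spec: PhantomSpec):
    """Watertight phantom mesh plus ground-truth vertex sets.

    Returns ``(mesh, truth)``; ``truth`` contains:

    * ``cusp_sets`` - per cusp, the crown vertices (height above
      0.35 x cusp height) nearest that cusp;
    * ``fusion_sets`` - per fused gap, the merged-saddle band where
      both neighboring cusps contribute strongly;
    * ``valley_sets`` - per gap, vertices on the inter-cusp valley
      floor;
    * ``cusp_tips`` - the apex position of each cusp;
    * ``occlusal_points`` - four crown-level reference points for
      occlusal-plane fitting;
    * ``cusp_label`` - per top-grid vertex, the nearest cusp (by x).
    """
    xs = _phantom_layout(spec)
    w = spec.cusp_width
    A = spec.cusp_height
    x_lo, x_hi = xs[0] - spec.margin, xs[-1] + spec.margin
    y_half = spec.margin
    nx = max(int(round((x_hi - x_lo) / spec.resolution)) + 1, 8)
    ny = max(int(round(2 * y_half / spec.resolution)) + 1, 8)
    gx = np.linspace(x_lo, x_hi, nx)
    gy = np.linspace(-y_half, y_half, ny)
    xx, yy = np.meshgrid(gx, gy, indexing="ij")

    contrib = np.stack(
        [A * np.exp(-(((xx - xc) ** 2) + yy**2) / w**2) for xc in xs]
    )
    zz = contrib.sum(axis=0)
    for g in range(spec.n_cusps - 1):
        if g in spec.fused:
            continue
        xg = 0.5 * (xs[g] + xs[g + 1])
        # interdental groove running the full bucco-lingual width
        zz = zz - spec.groove_depth * np.exp(
            -((xx - xg) ** 2) / (0.6 * w) ** 2
        )

    n_top = nx * ny

    def vid(i, j):
        return i * ny + j

    verts = [np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])]
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a, b = vid(i, j), vid(i + 1, j)
            c, d = vid(i + 1, j + 1), vid(i, j + 1)
            faces.append((a, c, b))
            faces.append((a, d, c))
    # boundary ring of the top grid, counter-clockwise seen from above
    ring = (
        [vid(i, 0) for i in range(nx)]
        + [vid(nx - 1, j) for j in range(1, ny)]
        + [vid(i, ny - 1) for i in range(nx - 2, -1, -1)]
        + [vid(0, j) for j in range(ny - 2, 0, -1)]
    )
    top_ring_pos = verts[0][ring]
    bottom = top_ring_pos.copy()
    bottom[:, 2] = -spec.base_depth
    verts.append(bottom)
    m = len(ring)
    for t in range(m):
        a = ring[t]
        b = ring[(t + 1) % m]
        a2 = n_top + t
        b2 = n_top + (t + 1) % m
        faces.append((a, b, b2))
        faces.append((a, b2, a2))
    # flat bottom: fan over the (convex) rectangle ring
    for t in range(1, m - 1):
        faces.append((n_top, n_top + t, n_top + t + 1))
    mesh = Mesh(np.vstack(verts), np.asarray(faces, dtype=np.int64))
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    if tm.volume < 0:
        mesh = Mesh(mesh.vertices, mesh.faces[:, ::-1].copy())

    # ---- ground truth on the top grid ------------------------------
    flat_contrib = contrib.reshape(spec.n_cusps, -1)
    total = verts[0][:, 2]
    nearest = np.argmin(
        np.abs(verts[0][:, 0][None, :] - xs[:, None]), axis=0
    )
    cusp_sets = []
    for c in range(spec.n_cusps):
        idx = np.flatnonzero((nearest == c) & (total > 0.35 * A))
        cusp_sets.append(frozenset(int(i) for i in idx))
    fusion_sets = []
    valley_sets = []
    for g in range(spec.n_cusps - 1):
        lo = np.minimum(flat_contrib[g], flat_contrib[g + 1])
        if g in spec.fused:
            idx = np.flatnonzero(lo > 0.25 * A)
            fusion_sets.append(frozenset(int(i) for i in idx))
        xg = 0.5 * (xs[g] + xs[g + 1])
        vx = verts[0][:, 0]
        vy = verts[0][:, 1]
        width = 0.45 * w if g in spec.fused else 0.6 * w
        vidx = np.flatnonzero(
            (np.abs(vx - xg) < width) & (np.abs(vy) < 1.2 * w)
        )
        valley_sets.append(frozenset(int(i) for i in vidx))
    tips = np.column_stack([xs, np.zeros_like(xs), np.full_like(xs, A)])
    for c, xc in enumerate(xs):
        # actual apex height includes neighbor contributions
        i = int(np.argmin(np.abs(gx - xc)))
        j = int(np.argmin(np.abs(gy)))
        tips[c] = [gx[i], gy[j], zz[i, j]]
    if spec.n_cusps >= 2:
        occ = np.array(
            [
                tips[0] + [0, 0.5 * w, 0],
                tips[0] - [0, 0.5 * w, 0],
                tips[-1] + [0, 0.5 * w, 0],
                tips[-1] - [0, 0.5 * w, 0],
            ]
        )
    else:
        occ = np.array(
            [
                tips[0] + [0.5 * w, 0, 0],
                tips[0] - [0.5 * w, 0, 0],
                tips[0] + [0, 0.5 * w, 0],
                tips[0] - [0, 0.5 * w, 0],
            ]
        )
    truth = {
        "cusp_sets": cusp_sets,
        "fusion_sets": fusion_sets,
        "valley_sets": valley_sets,
        "cusp_tips": tips,
        "cusp_centers_x": xs,
        "occlusal_points": occ,
        "cusp_label": nearest,
        "n_top": n_top,
    }
    return mesh, truth


# ---------------------------------------------------------------------
# hole cutting
# ---------------------------------------------------------------------


def cut_hole(mesh: Mesh, region: VertexRegion):
    """Delete triangles whose three vertices all lie in the region.

    Returns ``(new_mesh, loops)``.  Vertex indices are preserved (the
    new mesh keeps the full vertex array) so ground-truth labels stay
    valid; raises if the removal disconnects the mesh.
    """
    if len(region) == 0:
        return mesh.copy(), []
    member = np.zeros(mesh.n_vertices, dtype=bool)
    member[list(region.members)] = True
    inside = member[mesh.faces].all(axis=1)
    if not inside.any():
        return mesh.copy(), []
    keep = mesh.faces[~inside]
    new = Mesh(mesh.vertices.copy(), keep, validate=False)
    if _face_components(new) != _face_components(mesh):
        raise ValueError("hole cutting disconnects the mesh")
    return new, boundary_loops(new)


def _face_components(mesh: Mesh) -> int:
    seen = np.zeros(mesh.n_faces, dtype=bool)
    n = 0
    for f0 in range(mesh.n_faces):
        if seen[f0]:
            continue
        n += 1
        stack = [f0]
        seen[f0] = True
        while stack:
            f = stack.pop()
            tri = mesh.faces[f]
            for e0, e1 in ((0, 1), (1, 2), (2, 0)):
                for g in mesh.edge_face_indices(int(tri[e0]), int(tri[e1])):
                    if not seen[g]:
                        seen[g] = True
                        stack.append(g)
    return n
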