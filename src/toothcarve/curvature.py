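"""Per-vertex differential analysis of a triangle mesh.

Two estimators are provided:

* a local-frame **quadric fit**: the neighborhood of each vertex is
  expressed as a height field over the vertex tangent plane and a
  degree-2 polynomial surface is fitted by distance-weighted least
  squares; mean and Gaussian curvature follow from the fundamental
  forms of the fitted surface at the origin.  This is robust on noisy,
  irregularly triangulated scanner meshes.
* the cotangent **Laplace-Beltrami baseline** (Meyer-style discrete
  operators with mixed-area weighting), accurate on clean uniform
  meshes but noise-sensitive; kept for comparison.

Sign convention: curvatures are taken with respect to the outward
surface normal, positive where the surface bends away from the normal.
Hills and cusp tips therefore have minimum curvature > 0 and the
valley-like fusion/blending regions of a dental cast have minimum
curvature < 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .mesh_core import Mesh, neighborhood

log = logging.getLogger(__name__)


@dataclass
class QuadricFit:
    """Degree-2 height-field fit phi(u, v) = sum a_ks u^k v^s, k+s <= 2.

    ``coefficients`` are ordered (a00, a10, a01, a20, a11, a02).
    ``residual`` is the weighted sum of squared height errors; it is
    zero when the neighbors lie exactly on the quadric.
    """

    coefficients: np.ndarray
    k_used: int
    residual: float


@dataclass
class LocalFrame:
    """Right-handed orthonormal frame (u, v, phi) at a vertex.

    phi is the outward vertex normal; u is built deterministically from
    the global axis least parallel to phi, and v = phi x u.
    """

    origin: np.ndarray
    axis_u: np.ndarray
    axis_v: np.ndarray
    axis_phi: np.ndarray

    def to_local(self, points):
        d = np.atleast_2d(points) - self.origin
        return np.column_stack(
            (d @ self.axis_u, d @ self.axis_v, d @ self.axis_phi)
        )


@dataclass
class CurvatureField:
    """Per-vertex principal/mean/Gaussian curvatures with provenance."""

    kmin: np.ndarray
    kmax: np.ndarray
    kH: np.ndarray
    kG: np.ndarray
    estimator: str = "quadric"
    smoothed: bool = False


@dataclass
class CotangentWeights:
    """Cotangent edge weights and per-vertex area weights.

    ``edge_weight[(i, j)]`` (i < j) holds cot(alpha_ij) + cot(beta_ij),
    the sum over the one or two angles opposite the edge.  ``a_mixed``
    is the Meyer mixed area (Voronoi area with the obtuse-triangle
    special case) and ``ring_area`` the plain 1-ring triangle area sum.
    """

    edge_weight: dict
    a_mixed: np.ndarray
    ring_area: np.ndarray


def _cot(a, b):
    """Cotangent of the angle between vectors a and b."""
    cross = np.linalg.norm(np.cross(a, b))
    if cross < 1e-300:
        return 0.0
    return float(np.dot(a, b) / cross)


def cotangent_weights(mesh: Mesh) -> CotangentWeights:
    n = mesh.n_vertices
    edge_weight = {}
    a_mixed = np.zeros(n)
    ring_area = np.zeros(n)
    v = mesh.vertices
    for f in mesh.faces:
        i, j, k = (int(x) for x in f)
        pi, pj, pk = v[i], v[j], v[k]
        area = 0.5 * np.linalg.norm(np.cross(pj - pi, pk - pi))
        for x in (i, j, k):
            ring_area[x] += area
        # angles at each corner
        cots = {
            i: _cot(pj - pi, pk - pi),
            j: _cot(pi - pj, pk - pj),
            k: _cot(pi - pk, pj - pk),
        }
        for (a, b), opp in (((i, j), k), ((j, k), i), ((k, i), j)):
            key = (min(a, b), max(a, b))
            edge_weight[key] = edge_weight.get(key, 0.0) + cots[opp]
        # Meyer mixed area: Voronoi for non-obtuse triangles, else the
        # obtuse corner gets half the area and the others a quarter
        obtuse = [x for x, c in cots.items() if c < 0.0]
        if not obtuse:
            l2 = {
                i: np.dot(pj - pk, pj - pk),
                j: np.dot(pi - pk, pi - pk),
                k: np.dot(pi - pj, pi - pj),
            }
            # corner x gets 1/8 (|e1|^2 cot(opp1) + |e2|^2 cot(opp2))
            for x, y, z in ((i, j, k), (j, k, i), (k, i, j)):
                a_mixed[x] += (l2[z] * cots[z] + l2[y] * cots[y]) / 8.0
        else:
            for x in (i, j, k):
                a_mixed[x] += area / 2.0 if x in obtuse else area / 4.0
    return CotangentWeights(edge_weight, a_mixed, ring_area)


def area_weighted_normal(mesh: Mesh, i: int):
    fn = []
    v = mesh.vertices
    for fi in mesh.vertex_faces(i):
        f = mesh.faces[fi]
        n = np.cross(v[f[1]] - v[f[0]], v[f[2]] - v[f[0]])
        fn.append(n)  # cross product length = 2 area, so area-weighted
    if not fn:
        raise ValueError(f"vertex {i} has no incident triangle")
    s = np.sum(fn, axis=0)
    norm = np.linalg.norm(s)
    if norm < 1e-300:
        raise ValueError(f"degenerate normal at vertex {i}")
    return s / norm


def vertex_normal(mesh: Mesh, i: int, weights: CotangentWeights | None = None):
    """Unit outward normal at vertex ``i``.

    Interior vertices use the cotangent-weighted edge-vector sum
    normalized to unit length (the normalization absorbs the area
    coefficient); its sign is aligned with the area-weighted face
    normal, since the raw cotangent vector flips where the mean
    curvature changes sign.  Boundary vertices, and the degenerate
    case of a vanishing sum, fall back to the area-weighted face
    normal.
    """
    fallback = area_weighted_normal(mesh, i)
    if mesh.is_boundary_vertex(i):
        return fallback
    if weights is None:
        s = np.zeros(3)
        v = mesh.vertices
        ring = mesh.ordered_ring(i)
        for j in ring:
            w = 0.0
            for fi in mesh.edge_face_indices(i, j):
                f = mesh.faces[fi]
                opp = [int(x) for x in f if x != i and x != j][0]
                w += _cot(v[i] - v[opp], v[j] - v[opp])
            s += w * (v[i] - v[j])
    else:
        s = np.zeros(3)
        v = mesh.vertices
        for j in mesh.vertex_neighbors(i):
            key = (min(i, j), max(i, j))
            s += weights.edge_weight[key] * (v[i] - v[j])
    norm = np.linalg.norm(s)
    if norm < 1e-12 * max(1.0, np.linalg.norm(mesh.vertices[i])):
        log.debug("cotangent normal vanished at vertex %d; using area fallback", i)
        return fallback
    s /= norm
    if np.dot(s, fallback) < 0:
        s = -s
    return s


def local_frame(mesh: Mesh, i: int, normal=None) -> LocalFrame:
    phi = vertex_normal(mesh, i) if normal is None else normal
    # deterministic tangent: global axis least parallel to the normal
    axis = int(np.argmin(np.abs(phi)))
    e = np.zeros(3)
    e[axis] = 1.0
    u = e - np.dot(e, phi) * phi
    u /= np.linalg.norm(u)
    v = np.cross(phi, u)
    return LocalFrame(
        origin=mesh.vertices[i].copy(), axis_u=u, axis_v=v, axis_phi=phi
    )


def _knn_from_rings(mesh: Mesh, i: int, k: int, n_start: int = 2):
    """k nearest n-ring neighbors of vertex i (center excluded)."""
    n = n_start
    while True:
        cand = neighborhood(mesh, i, n).members - {i}
        if len(cand) >= k or n > n_start + 6:
            break
        n += 1
    cand = np.fromiter(cand, dtype=np.int64)
    d = np.linalg.norm(mesh.vertices[cand] - mesh.vertices[i], axis=1)
    order = np.argsort(d, kind="stable")
    return cand[order[: min(k, len(cand))]]


def fit_local_quadric(
    mesh: Mesh,
    i: int,
    k: int = 18,
    frame: LocalFrame | None = None,
    allow_rank_deficient: bool = False,
) -> QuadricFit:
    """Weighted least-squares degree-2 fit over the k nearest ring neighbors.

    Neighbors are mapped into the vertex local frame; the sample at
    q_j is weighted exp(-d_j / max_j d_j) with d_j its distance from
    the mapped center.  Rank-deficient configurations retry with a
    wider ring (up to 3 enlargements); with ``allow_rank_deficient``
    the minimum-norm solution of the last attempt is accepted instead
    of raising (used for whole-field computation, where sharp
    artificial creases such as a phantom's box rim are genuinely
    degenerate).
    """
    if frame is None:
        frame = local_frame(mesh, i)
    last_err = None
    last_fit = None
    for attempt in range(4):
        idx = _knn_from_rings(mesh, i, k + 4 * attempt, n_start=2 + attempt)
        if len(idx) < 6:
            last_err = ValueError(
                f"vertex {i}: only {len(idx)} neighbors, need >= 6"
            )
            continue
        q = frame.to_local(mesh.vertices[idx])
        u, v, phi = q[:, 0], q[:, 1], q[:, 2]
        d = np.linalg.norm(q, axis=1)
        dmax = d.max()
        w = np.exp(-d / dmax) if dmax > 0 else np.ones_like(d)
        A = np.column_stack(
            (np.ones_like(u), u, v, u * u, u * v, v * v)
        )
        sw = np.sqrt(w)
        coeff, _, rank, _ = np.linalg.lstsq(A * sw[:, None], phi * sw)
        resid = float(np.sum(w * (A @ coeff - phi) ** 2))
        if rank < 6:
            last_err = np.linalg.LinAlgError(
                f"vertex {i}: rank-deficient quadric fit (rank {rank})"
            )
            last_fit = QuadricFit(
                coefficients=coeff, k_used=len(idx), residual=resid
            )
            continue
        return QuadricFit(coefficients=coeff, k_used=len(idx), residual=resid)
    if allow_rank_deficient and last_fit is not None:
        return last_fit
    raise last_err


def curvatures_from_quadric(fit: QuadricFit):
    """(kH, kG) of the fitted height field at the origin.

    Uses the first and second fundamental forms of
    S(u, v) = (u, v, phi(u, v)); the mean curvature is negated relative
    to the raw Monge form so that surfaces bending away from the
    outward normal count as positive (dome-positive convention).
    """
    _, a10, a01, a20, a11, a02 = fit.coefficients
    pu, pv = a10, a01
    puu, puv, pvv = 2 * a20, a11, 2 * a02
    E = 1 + pu * pu
    F = pu * pv
    G = 1 + pv * pv
    W = math.sqrt(1 + pu * pu + pv * pv)
    L, M, N = puu / W, puv / W, pvv / W
    denom = E * G - F * F
    kG = (L * N - M * M) / denom
    kH = -(E * N - 2 * F * M + G * L) / (2 * denom)
    return kH, kG


def principal_from_mean_gauss(kH, kG, tol=1e-9):
    disc = kH * kH - kG
    if disc < -tol:
        raise ValueError(
            f"kH^2 - kG = {disc:.3e} < 0: no real principal curvatures"
        )
    root = math.sqrt(max(disc, 0.0))
    return kH - root, kH + root


def principal_curvatures(
    mesh: Mesh, i: int, k: int = 18, allow_rank_deficient: bool = False
):
    """(kmin, kmax, kH, kG) at vertex ``i`` from the quadric estimator."""
    fit = fit_local_quadric(
        mesh, i, k=k, allow_rank_deficient=allow_rank_deficient
    )
    kH, kG = curvatures_from_quadric(fit)
    kmin, kmax = principal_from_mean_gauss(kH, kG)
    return kmin, kmax, kH, kG


def meyer_curvature(mesh: Mesh, i: int, weights: CotangentWeights | None = None):
    """(kH, kG) from the cotangent Laplace-Beltrami baseline.

    Mean curvature is half the norm of the discrete mean-curvature
    vector with mixed-area weighting, signed by its alignment with the
    outward normal; Gaussian curvature is the angle deficit divided by
    the mixed area.  Undefined on boundary vertices.
    """
    if mesh.is_boundary_vertex(i):
        raise ValueError(f"vertex {i} is on the boundary; baseline undefined")
    if weights is None:
        weights = cotangent_weights(mesh)
    v = mesh.vertices
    s = np.zeros(3)
    for j in mesh.vertex_neighbors(i):
        key = (min(i, j), max(i, j))
        s += weights.edge_weight[key] * (v[i] - v[j])
    K = s / (2.0 * weights.a_mixed[i])
    n = area_weighted_normal(mesh, i)
    kH = 0.5 * np.linalg.norm(K) * (1.0 if np.dot(K, n) >= 0 else -1.0)
    angle_sum = 0.0
    for fi in mesh.vertex_faces(i):
        f = mesh.faces[fi]
        others = [int(x) for x in f if x != i]
        a = v[others[0]] - v[i]
        b = v[others[1]] - v[i]
        angle_sum += math.atan2(
            np.linalg.norm(np.cross(a, b)), float(np.dot(a, b))
        )
    kG = (2.0 * math.pi - angle_sum) / weights.a_mixed[i]
    return float(kH), float(kG)


def curvature_field(
    mesh: Mesh,
    k: int = 18,
    estimator: str = "quadric",
    smooth_passes: int = 0,
) -> CurvatureField:
    """Compute curvatures at every vertex.

    With the Meyer baseline, boundary vertices receive NaN (the
    operator is undefined there).
    """
    n = mesh.n_vertices
    kmin = np.empty(n)
    kmax = np.empty(n)
    kH = np.empty(n)
    kG = np.empty(n)
    if estimator == "quadric":
        for i in range(n):
            if not mesh.vertex_faces(i):
                kmin[i] = kmax[i] = kH[i] = kG[i] = np.nan
                continue
            kmin[i], kmax[i], kH[i], kG[i] = principal_curvatures(
                mesh, i, k=k, allow_rank_deficient=True
            )
    elif estimator == "meyer":
        w = cotangent_weights(mesh)
        for i in range(n):
            if not mesh.vertex_faces(i) or mesh.is_boundary_vertex(i):
                kmin[i] = kmax[i] = kH[i] = kG[i] = np.nan
                continue
            h, g = meyer_curvature(mesh, i, weights=w)
            kH[i], kG[i] = h, g
            try:
                kmin[i], kmax[i] = principal_from_mean_gauss(h, g)
            except ValueError:
                # noisy baseline can report kH^2 < kG; clamp to umbilic
                kmin[i] = kmax[i] = h
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    field = CurvatureField(kmin, kmax, kH, kG, estimator=estimator)
    for _ in range(smooth_passes):
        field = smooth_curvature(mesh, field)
    return field


def smooth_curvature(
    mesh: Mesh, field: CurvatureField, include_center: bool = False
) -> CurvatureField:
    """One pass of inverse-distance 1-ring smoothing of the curvatures.

    Each vertex value is replaced by the weighted combination of its
    1-ring neighbor values with weights 1/||v_i - v_j||, normalized to
    sum to one so a constant field stays constant.  The center's own
    value is excluded by default; ``include_center`` adds it with the
    capped coincident-vertex weight.  kmin and kmax are smoothed and
    kH, kG rederived so the algebraic relations between the four
    channels survive smoothing.
    """
    v = mesh.vertices
    new_min = field.kmin.copy()
    new_max = field.kmax.copy()
    for i in range(mesh.n_vertices):
        idx = list(mesh.vertex_neighbors(i))
        if not idx:
            continue
        d = np.linalg.norm(v[idx] - v[i], axis=1)
        w = np.where(d > 1e-12, 1.0 / np.maximum(d, 1e-12), 1e12)
        vals_min = field.kmin[idx]
        vals_max = field.kmax[idx]
        if include_center:
            w = np.append(w, 1e12)
            vals_min = np.append(vals_min, field.kmin[i])
            vals_max = np.append(vals_max, field.kmax[i])
        ok = np.isfinite(vals_min)
        if not ok.any():
            continue
        wn = w[ok] / w[ok].sum()
        new_min[i] = float(wn @ vals_min[ok])
        new_max[i] = float(wn @ vals_max[ok])
    lo = np.minimum(new_min, new_max)
    hi = np.maximum(new_min, new_max)
    return CurvatureField(
        kmin=lo,
        kmax=hi,
        kH=(lo + hi) / 2.0,
        kG=lo * hi,
        estimator=field.estimator,
        smoothed=True,
    )
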