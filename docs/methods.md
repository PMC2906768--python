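# Methods

`toothcarve` implements an integrated single-tooth modeling scheme for
3D dental casts represented as oriented 2-manifold triangle meshes:
curvature-based feature-region analysis, removal of the fusion regions
between adjoining teeth, per-tooth restoration of the resulting holes,
and skeleton-based extraction of the segmentation boundary along which
single teeth are separated from the cast. This note records the models,
the parameters that matter, the numerical choices, and what the
synthetic phantoms do and do not show.

## Mesh model

All stages operate on an indexed triangle mesh with consistent winding:
every edge borders one or two triangles, and the two triangles across
an interior edge traverse it in opposite directions. Scanner meshes
(STL/OBJ/PLY, mm units) are loaded through `trimesh`; STL triangle
soup is welded with a duplicate-vertex tolerance of 1e-9 x the
bounding-box diagonal (scanner duplicates are bit-identical in
practice). Boundary loops are oriented following the winding of their
unique incident triangle, which fixes the normal convention for hole
filling. `cut_hole` keeps the full vertex array (removed-region
vertices become unreferenced) so that ground-truth vertex labels stay
valid across the pipeline; Euler-characteristic checks are therefore
made on the referenced sub-surface.

## Curvature estimation

The per-vertex estimator fits a degree-2 height field
φ(u, v) = Σ a_ks u^k v^s (k + s ≤ 2) over the vertex's local frame by
weighted least squares. The frame normal is the cotangent-weighted
edge-vector sum, normalized (the printed area coefficient cancels
under normalization) and sign-aligned with the area-weighted face
normal, because the raw cotangent vector is the mean-curvature vector
and flips sign with the sign of H. Tangent axes are built
deterministically from the global axis least parallel to the normal;
curvatures are frame-invariant, so any orthonormal pair works. The
k = 18 nearest ring neighbors (within the paper-stated 16–20 band) are
collected by growing the n-ring until enough candidates exist, and
each sample is weighted exp(−d_j / max_j d_j) by its distance from the
mapped center. Mean and Gaussian curvature come from the fundamental
forms of the fitted surface at the origin.

Sign convention: curvatures are measured with respect to the outward
normal, **positive where the surface bends away from it**. Cusp tips
(domes) then have κ_min > 0 and the fusion/blending valleys κ_min < 0;
a unit sphere has κ_1 = κ_2 = +1. Principal curvatures are
κ_min/max = κ_H ∓ sqrt(κ_H² − κ_G), with the radicand clamped at zero
when within −1e-9 (round-off at umbilics).

Rank-deficient neighborhoods (all samples on two straight lines — this
happens on the phantom's artificial box rim) retry with a wider ring
up to 3 times; whole-field computation then accepts the minimum-norm
solution, since curvature on such a crease is not meaningful anyway.

The comparison baseline is the cotangent Laplace–Beltrami operator
with Meyer mixed-area weights (Voronoi area, with the obtuse-triangle
special case) for κ_H and the angle-deficit formula for κ_G. It is
undefined on boundary vertices (NaN in field output). On clean uniform
meshes it is accurate; on noisy meshes the quadric fit is markedly
more robust, which the acceptance suite verifies on noisy tori.

Curvature smoothing replaces each vertex value by the
inverse-distance-weighted combination of its 1-ring neighbor values
(θ_ij = 1/‖v_i − v_j‖). The printed weights do not sum to one, which
would rescale a constant field, so they are normalized per vertex; the
center vertex is excluded by default (configurable). κ_min and κ_max
are smoothed and κ_H, κ_G rederived so the algebraic relations among
the four channels survive smoothing. Coincident-vertex weights are
capped at 1e12.

## Feature regions and morphology

The feature region is F′ = {i : κ_min(v_i) < t}. The threshold is
exposed both as an absolute value (mm⁻¹) and as an empirical quantile
of the κ_min distribution (default q = 0.15), the latter being
scale-free across resolutions. Components are induced by mesh edges;
components below `min_component` vertices (default 30) are removed.
The four morphology operators act on vertex sets through n-ring
neighborhoods: dilation is the union of member n-rings, erosion keeps
vertices whose whole n-ring is inside, opening is erosion-then-
dilation and closing the reverse (the standard compositions, matching
the described effects: erosion deletes branches, dilation attracts rim
vertices). The default schedule close–open–close–open suits wide,
noisy regions; **for thin valley features (one or two vertices wide,
e.g. the seam between two restored teeth at moderate resolution) any
opening step is destructive and a closing-only schedule should be
used** — the end-to-end phantom analysis does exactly that.

## Surface paths and spatial polygons

Interactive picking is replaced by direction tracing: from the current
point, the line to the destination is advanced by cutting the current
triangle with the normal section (the plane spanned by the remaining
direction and the local normal); among forward exit points the one
with the smallest angle to the goal direction wins, ties going to the
farther point so progress is guaranteed. Points hitting a mesh vertex
continue with the full vertex star as carrier. On a flat mesh the
trace reproduces the Euclidean segment to round-off; on a sphere the
cutting plane contains the great circle, so the path approximates the
geodesic (0.1% length error on an order-4 icosphere in our tests,
comfortably within the 3% contract). Cost is linear in path length.

A closed fence of traced paths selects a region: triangles the fence
passes through are barriers, a seed flood fill (default seed: the
triangle nearest the anchor centroid) grows the interior, and the
*enclosed* set keeps only triangles whose three vertices fall strictly
inside the fence polyline. When the fence runs exactly along mesh
edges, those edges also block the flood. A fence of a few triangles
that encloses no complete triangle yields an empty selection.

## Hole restoration

A removed fusion region leaves a saddle-shaped hole shared by two
teeth; filling it as one patch would average the two teeth's boundary
data, so the hole is divided first.

**Occlusal plane.** Total-least-squares plane (SVD) through four
crown reference points, normal oriented toward the crowns via an
up-hint.

**Bridging.** The two strongest cyclic local maxima of the boundary's
distance-to-plane profile are the bridge endpoints; the second maximum
must lie on the opposite arc (minimum cyclic separation n/4, relaxed
to 2 before erroring) so the split respects the buccal/lingual sides.
The bridge chord is subdivided at the surrounding-mesh edge length and
the chain vertices are shared by both subloops: with a single long
bridge edge the seam between the restored teeth would carry almost no
vertices and the re-analysis stage could not see the inter-tooth
valley. |B¹| + |B²| = |B| + 2 counts the raw split.

**Spanning triangulation (P^min).** Advancing-front ear clipping over
the cyclic boundary, driven by a weight with case priority: −∞ when
the candidate violates the non-intersection projection condition (its
new edge, projected with the existing incident edges onto each
endpoint's tangent plane, must not cross any of them away from shared
vertices, tolerance 1e-12 relative); l_bigger = (|NeiT¹(i)|/8)·R_C
when the apex already carries more than 8 triangles (remove it first);
l_less = −(π/A(v_i))·R_C when the apex angle sum is a sharp open
corner 0 < A(v_i) < απ with α = 1.2; otherwise minus the candidate's
perimeter. A(v_i) counts all current incident triangles — surrounding
mesh and accumulated patch alike — and R_C is the bounding-sphere
radius. The ordered weight set lives in a lazy-deletion binary heap;
each clip refreshes the four triples whose weights can change, so the
run is O(N log N) and provably identical to a quadratic full-rescan
reference with the same lowest-index tie rule (tested on random
loops). If every remaining weight is −∞ the least-perimeter ear is
accepted once without the projection test (logged); this cannot occur
on well-formed boundaries but prevents deadlock on pathological ones.
The result uses exactly the |B| boundary vertices and |B| − 2
triangles.

**Refinement (P^refine).** Triangles whose mean edge length exceeds
c = 1.5 x the surrounding mean edge length ("surrounding" = edges
within 2 rings of the hole) are 1-to-3 split at the centroid; after
each round, interior edges whose opposite angles sum beyond π are
flipped (boundary edges never). Splitting is skipped when the new
spokes would be shorter than 0.45 x the target — without this guard a
boundary edge longer than the target (the bridge chord) cannot be
removed by flips and splitting never terminates. Flips skip faces
already modified in the pass and diagonals that already exist.

**k-harmonic reshaping (P^deform).** Free interior vertices solve
Δ̄^k x = 0 with Δ the cotangent Laplacian scaled by 2/Area(v_i)
(full 1-ring area, as specified; a positive diagonal scale changes
nothing for k = 1 and defines the operator used verbatim for k ≥ 2).
The patch is glued into the mesh, weights are computed once from the
glued P^refine geometry and frozen, and the constrained sparse system
is solved by direct factorization (SuperLU); the C^{k−1} boundary
conditions are realized implicitly by the surrounding constraint
vertices entering the k-ring stencil of the free rows. k = 1/2/3 give
membrane, thin-plate, and curvature-variation-minimizing fills; teeth
use k = 2. Residuals above 1e-8 x bounding-box diagonal (relative)
raise.

**Blending and interference.** P^final = P^refine +
λ(P^deform − P^refine). λ starts at 1 and decreases by τ ≤ 0.01 until
the two sub-patches stop intersecting; λ is not allowed below 0.8 (an
error carries both patches for inspection). Intersection uses a
Möller-style triangle–triangle interval test with a coplanar 2D
fallback (tolerance 1e-12), excluding pairs that share a vertex by
position — the patches legitimately meet along the bridge chain. An
axis-aligned-box prefilter keeps the pair count manageable.

## Tooth separation

Re-analysis of the restored cast yields the blending region between
teeth and gingiva. Vertex complexity CP(i) is the cyclic sum of
absolute successive differences of the 0/1 membership pattern around
the counter-clockwise-ordered 1-ring (wrap term included; CP is even
and twice the number of membership runs). Center vertices (full member
ring) are never removed — that would punch a spurious ring — and
complex vertices (CP ≥ 4) are never removed — that would disconnect
the region. A vertex is peeled exactly when CP = 2: its member
neighbors form one contiguous arc joined by mesh edges, so removal
preserves local connectivity. (The satellite-of-a-center candidate
set reaches a fixpoint at two-vertex-wide bands on structured meshes,
because no vertex has a full interior ring there; the CP = 2 rule
continues to width one while honoring the same preservation
constraints.) Removal order is ascending (distance-to-boundary BFS
depth, CP, hashed index): depth-ordering is the standard thinning
discipline that keeps the skeleton on the medial line of the band, and
the index hash removes the directional sweep bias a raw index order
has on structured grids. The order is deterministic.

Pruning deletes degree-≤1 vertices iteratively (open branches of
non-target regions disappear on their own), then drops closed rings
shorter than `min_ring` (default 8; this automates the interactive
removal of small redundant rings). Components that remain 2-regular
are ordered into rings; components where two tooth boundaries share an
inter-dental path (junction vertices of degree ≥ 3 — the generic
outcome when adjacent teeth share one valley line) are kept whole as
ring complexes.

Separation flood-fills faces without crossing any edge joining two
adjacent skeleton members; ring vertices are duplicated into each part
so teeth carry their cervical margin. Single-triangle slivers pinched
off at skeleton junctions (< 10 faces) are folded into their largest
neighbor. The largest part is taken as the base/gingiva — a heuristic,
not an anatomical rule — and every other part is one tooth. A skeleton
that fails to split the surface raises.

## Synthetic phantoms

Real scanned casts are not redistributable, so every stage is
validated on procedural stand-ins:

* **Torus** (wheel radius R = 2, tube radius r = 1 by default) with
  closed-form principal curvatures κ_1 = 1/r,
  κ_2 = cos v/(R + r cos v) as the estimator oracle. Noise level h
  displaces vertices along the analytic normal by a zero-mean Gaussian
  with σ = h x mean edge length; h is treated as unitless relative to
  mesh density (the robustness comparison is invariant to this
  convention since both estimators see the same mesh).
* **Dental phantom**: a heightfield of Gaussian cusps
  (height 5 mm, width 2.4 mm) on a flat gum plane, closed into a
  watertight slab. Fused pairs are spaced 3.4 mm so the bumps merge
  with no gap (the fusion saddle); normal gaps are 7 mm with a 0.6 mm
  interdental groove running the full bucco-lingual width. Ground
  truth includes per-cusp crown vertex sets (height > 0.35 x cusp
  height, nearest cusp), fusion bands (where both neighboring cusps
  contribute > 0.25 x height), valley floors, cusp tips, and four
  occlusal reference points. At the default 0.35 mm resolution the
  κ_min field separates cusps (> 0) from valleys (< 0) cleanly.

The phantom emulates the geometry of fused and blending regions, not
scanner artifacts: no holes from occlusion, no anisotropic noise, no
texture, and its gum is a plane inside a box rather than anatomical
soft tissue (the box rim is an artificial crease the curvature stage
must tolerate, which is why rank-deficient fits degrade gracefully).
Passing the end-to-end test shows the pipeline's stages compose
correctly under realistic dental geometry; it does not certify
accuracy on clinical scans, for which the original work reports
physical-cast comparisons that require data this package cannot ship.

### End-to-end study conditions

The four-cusp, two-fused-pair phantom at 0.35 mm resolution is
analyzed with an absolute threshold κ_min < −0.25 mm⁻¹, a closing-only
morphology schedule, min_component = 30, one smoothing pass, k = 18,
fairing order k = 2, λ from 1.0 with τ = 0.01, min_ring = 8. The
absolute threshold reflects the phantom's known curvature scale (its
valley floors sit well below −0.3 mm⁻¹, flat gum near 0); the
closing-only schedule preserves the one-vertex-wide seam valleys
between restored teeth. Per-tooth agreement is measured against the
ground-truth crown sets: the fraction of a tooth's labeled vertices
carrying its majority cusp label.

## Known limitations

* The projection condition is evaluated against the edges incident to
  the three candidate vertices, not a full local arrangement; extreme
  self-overlapping boundaries may need the logged least-perimeter
  fallback.
* `refine_patch` never splits boundary edges, so a patch bordered by
  edges much longer than the target density keeps a few large
  triangles next to them.
* Ring extraction inside a junction-bearing skeleton complex is
  resolved by cutting along all retained skeleton edges rather than
  enumerating explicit per-tooth rings.
* The base-versus-tooth designation ("largest part is the base") is a
  heuristic; a cast with a tooth larger than the visible gingiva would
  need an explicit base seed.
* Curvature field computation is O(V) small dense solves in Python;
  meshes beyond ~10^5 vertices will want batching.
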