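"""Feature-region extraction and mesh mathematical morphology.

A feature region F' is the vertex-index set where the (smoothed)
minimum curvature falls below a threshold: the valley-like fusion
regions between adjoining teeth and the blending regions between teeth
and gingiva.  Raw thresholded regions contain small speckles and
pinholes, which are cleaned by small-component removal and by the four
vertex-set morphology operators (dilation, erosion, opening, closing)
defined on n-ring neighborhoods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curvature import CurvatureField
from .mesh_core import Mesh, neighborhood


@dataclass
class VertexRegion:
    """A vertex-index subset of a mesh with its connected components.

    Adjacency is induced by mesh edges between member vertices.
    """

    mesh: Mesh
    members: frozenset

    def __contains__(self, i):
        return i in self.members

    def __len__(self):
        return len(self.members)

    def components(self):
        """Connected components of the induced vertex subgraph."""
        remaining = set(self.members)
        comps = []
        while remaining:
            seed = remaining.pop()
            comp = {seed}
            frontier = [seed]
            while frontier:
                i = frontier.pop()
                for j in self.mesh.vertex_neighbors(i):
                    if j in remaining:
                        remaining.discard(j)
                        comp.add(j)
                        frontier.append(j)
            comps.append(frozenset(comp))
        return comps


def threshold_region(
    mesh: Mesh,
    field: CurvatureField,
    t: float | None = None,
    quantile: float = 0.15,
) -> VertexRegion:
    """Vertices with kmin below a threshold.

    With ``t`` given, F' = {i : kmin(v_i) < t}.  Otherwise ``t`` is the
    empirical ``quantile`` of the kmin distribution, which is scale-free
    across mesh resolutions (the absolute threshold a given scan needs
    depends on its units and noise level).
    """
    kmin = field.kmin
    if t is None:
        t = float(np.nanquantile(kmin, quantile))
    members = frozenset(int(i) for i in np.flatnonzero(kmin < t))
    return VertexRegion(mesh=mesh, members=members)


def remove_small_components(region: VertexRegion, min_vertices: int) -> VertexRegion:
    """Drop components with strictly fewer than ``min_vertices`` members."""
    keep = [c for c in region.components() if len(c) >= min_vertices]
    members = frozenset().union(*keep) if keep else frozenset()
    return VertexRegion(mesh=region.mesh, members=members)


def dilate(region: VertexRegion, n: int = 1) -> VertexRegion:
    """Union of the n-ring neighborhoods of all members."""
    if n < 1:
        raise ValueError("ring order must be >= 1")
    mesh = region.mesh
    out = set()
    for j in region.members:
        out |= neighborhood(mesh, j, n).members
    return VertexRegion(mesh=mesh, members=frozenset(out))


def erode(region: VertexRegion, n: int = 1) -> VertexRegion:
    """Vertices whose entire n-ring neighborhood lies inside the region."""
    if n < 1:
        raise ValueError("ring order must be >= 1")
    mesh = region.mesh
    # only members can survive (every n-ring contains its center)
    out = {
        k
        for k in region.members
        if neighborhood(mesh, k, n).members <= region.members
    }
    return VertexRegion(mesh=mesh, members=frozenset(out))


def open_region(region: VertexRegion, n: int = 1) -> VertexRegion:
    """Opening: erosion then dilation; removes thin spurs and speckle."""
    return dilate(erode(region, n), n)


def close_region(region: VertexRegion, n: int = 1) -> VertexRegion:
    """Closing: dilation then erosion; fills pinholes, smooths the rim."""
    return erode(dilate(region, n), n)


def apply_morphology(region: VertexRegion, schedule) -> VertexRegion:
    """Apply a schedule like [("close", 1), ("open", 1), ...] in order.

    Repeated opening/closing filters curvature-noise speckle from the
    feature regions while keeping their shape.
    """
    ops = {
        "dilate": dilate,
        "erode": erode,
        "open": open_region,
        "close": close_region,
    }
    for name, n in schedule:
        region = ops[name](region, n)
    return region


def parse_morphology(text: str):
    """Parse a schedule string like ``"close:1,open:1,close:1,open:1"``."""
    schedule = []
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        name, _, n = part.partition(":")
        schedule.append((name.strip(), int(n) if n else 1))
    return schedule


DEFAULT_MORPHOLOGY = (("close", 1), ("open", 1), ("close", 1), ("open", 1))
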