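"""End-to-end orchestration of the single-tooth modeling scheme.

The five-stage workflow: (1) load/digitize the dental mesh, (2)
analyze curvature and select/remove the fusion regions between
adjoining teeth, (3) restore each single-tooth shape across the
resulting holes, (4) re-analyze and extract the blending region
between teeth and soft tissue, (5) thin it to the segmentation
boundary and separate the teeth.

Interactive steps of a clinical workflow (polygon picking, manual
removal of redundant rings) are replaced by programmatic inputs:
caller-supplied fusion-region vertex sets (or spatial-polygon anchor
lists) and the ``min_ring`` threshold.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from . import curvature as curv
from . import hole_restore as hr
from . import phantoms
from . import regions as rg
from . import tooth_segment as ts
from .mesh_core import Mesh, load_mesh, save_mesh
from .regions import VertexRegion


@dataclass
class PipelineConfig:
    """All tunable knobs of the pipeline with validated defaults."""

    k_neighbors: int = 18
    smooth_passes: int = 1
    threshold_quantile: float = 0.15
    threshold_absolute: float | None = None
    min_component: int = 30
    morphology: tuple = rg.DEFAULT_MORPHOLOGY
    alpha: float = 1.2
    k_order: int = 2
    lam_max: float = 1.0
    tau: float = 0.01
    min_ring: int = 8
    seed: int = 0

    def validate(self):
        if not 16 <= self.k_neighbors <= 30:
            raise ValueError("k_neighbors outside the sensible 16..30 band")
        if not 0 < self.threshold_quantile < 1:
            raise ValueError("threshold_quantile must be in (0, 1)")
        if self.tau > 0.01:
            raise ValueError("adjustment step tau should not be bigger than 0.01")
        if self.k_order not in (1, 2, 3):
            raise ValueError("fairing order k must be 1, 2, or 3")
        if not 0 < self.lam_max <= 1.0:
            raise ValueError("lambda_max must be in (0, 1]")
        if self.min_ring < 3:
            raise ValueError("min_ring must be >= 3")
        return self


def extract_feature_region(mesh: Mesh, config: PipelineConfig) -> VertexRegion:
    field_ = curv.curvature_field(
        mesh,
        k=config.k_neighbors,
        estimator="quadric",
        smooth_passes=config.smooth_passes,
    )
    region = rg.threshold_region(
        mesh,
        field_,
        t=config.threshold_absolute,
        quantile=config.threshold_quantile,
    )
    region = rg.apply_morphology(region, config.morphology)
    region = rg.remove_small_components(region, config.min_component)
    return region


def run_pipeline(
    mesh: Mesh,
    config: PipelineConfig | None = None,
    fusion_regions=None,
    occlusal_points=None,
):
    """Run the full scheme on an in-memory mesh.

    ``fusion_regions`` is a list of vertex-index sets to remove and
    restore (programmatic replacement of interactive selection); when
    omitted, the restoration stage is skipped and segmentation runs on
    the mesh as is.  ``occlusal_points`` (4 x 3) is required whenever
    fusion regions are given.

    Returns ``(report, result)`` where result bundles the restored
    mesh, the skeleton, and the separation.
    """
    config = (config or PipelineConfig()).validate()
    report = {"stages": []}
    t0 = time.perf_counter()

    def stage(name, **info):
        report["stages"].append(
            {"stage": name, "elapsed_s": round(time.perf_counter() - t0, 3), **info}
        )

    restored = mesh
    lam_values = []
    n_restored = 0
    if fusion_regions:
        if occlusal_points is None:
            raise ValueError("occlusal_points required to restore fusion holes")
        plane = hr.fit_occlusal_plane(occlusal_points)
        for members in fusion_regions:
            region = VertexRegion(mesh=restored, members=frozenset(members))
            restored, loops = phantoms.cut_hole(restored, region)
            for loop in loops:
                p1, p2, restored, lam = hr.restore_hole(
                    restored,
                    loop,
                    plane,
                    k=config.k_order,
                    lam_max=config.lam_max,
                    tau=config.tau,
                )
                lam_values.append(lam)
                n_restored += 1
        stage(
            "restoration",
            holes_restored=n_restored,
            lambda_values=lam_values,
            watertight=restored.is_watertight(),
        )

    region = extract_feature_region(restored, config)
    stage("feature-region", vertices=len(region), components=len(region.components()))

    skeleton = ts.skeletonize(region)
    skeleton = ts.prune(skeleton, min_ring=config.min_ring)
    stage(
        "skeleton",
        rings=len(skeleton.rings),
        ring_complexes=len(skeleton.complexes),
        skeleton_vertices=len(skeleton.retained_members()),
    )

    if skeleton.retained_members():
        separation = ts.separate(restored, skeleton)
    else:
        separation = ts.SeparationResult(
            teeth=[],
            base=restored.copy(),
            tooth_face_indices=[],
            base_face_indices=np.arange(restored.n_faces),
        )
    stage("separation", teeth=len(separation.teeth))

    report["holes_restored"] = n_restored
    report["lambda_values"] = lam_values
    report["teeth"] = len(separation.teeth)
    result = {
        "mesh": restored,
        "region": region,
        "skeleton": skeleton,
        "separation": separation,
    }
    return report, result
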