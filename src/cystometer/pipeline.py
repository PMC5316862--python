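"""End-to-end analysis of one well's focal-plane stack."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assembly import (
    CystRecord,
    WellSummary,
    estimate_volume,
    link_across_planes,
    params_fingerprint,
    summarize_well,
)
from .features import FilterThresholds, ObjectFeatures, compute_features, filter_objects
from .geometry import ImageStack
from .segmentation import SegmentationParams, segment_plane


@dataclass
class StackAnalysis:
    """Everything the per-well pipeline produced."""

    well_id: str
    kept: list[ObjectFeatures]
    rejected: list[tuple[ObjectFeatures, str]]
    cysts: list[CystRecord]
    summary: WellSummary
    per_plane_object_counts: list[int] = field(default_factory=list)


def analyze_stack(
    stack: ImageStack,
    params: SegmentationParams | None = None,
    thresholds: FilterThresholds | None = None,
    artifact_masks: list[np.ndarray | None] | None = None,
    link_mode: str = "overlap",
) -> StackAnalysis:
    """Segment every plane, filter objects, link across z and summarise.

    ``artifact_masks`` optionally supplies one mask per plane (None entries
    allowed).  Returns a :class:`StackAnalysis`; cyst volumes are in um^3
    using the stack geometry's pixel size.
    """
    params = params or SegmentationParams()
    thresholds = thresholds or FilterThresholds()
    if artifact_masks is not None and len(artifact_masks) != len(stack):
        raise ValueError("need one artifact mask entry per plane")

    all_objects: list[ObjectFeatures] = []
    per_plane_counts: list[int] = []
    for i in range(len(stack)):
        mask = artifact_masks[i] if artifact_masks is not None else None
        labels = segment_plane(stack[i], params, mask)
        objs = compute_features(labels, plane_index=i)
        per_plane_counts.append(len(objs))
        all_objects.extend(objs)

    kept, rejected = filter_objects(all_objects, thresholds)
    cysts = link_across_planes(kept, mode=link_mode)
    cysts = [estimate_volume(c, stack.geometry.pixel_size) for c in cysts]
    fp = params_fingerprint(params, thresholds, stack.geometry)
    summary = summarize_well(cysts, stack.well_id, fingerprint=fp)
    return StackAnalysis(
        well_id=stack.well_id,
        kept=kept,
        rejected=rejected,
        cysts=cysts,
        summary=summary,
        per_plane_object_counts=per_plane_counts,
    )
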