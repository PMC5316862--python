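"""Z-axis deduplication of objects into cysts, volumes, and summaries.

A cyst larger than the focal-plane spacing appears in several consecutive
planes; counting it once requires linking co-located objects across the
z-axis.  Two kept objects in *adjacent* planes belong to the same cyst when
their pixel footprints overlap by at least one pixel (a centroid-containment
mode is available); cysts are the connected components of this
adjacent-plane overlap graph.  Each cyst's volume is then estimated as a
sphere, V = (4/3) * pi * r**3, with r the mean radius of the cyst's
largest-area cross-section.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .features import FilterThresholds, ObjectFeatures


@dataclass
class CystRecord:
    """A deduplicated cyst: its per-plane member objects and volume estimate."""

    members: list[ObjectFeatures]  # ordered by plane index
    representative_radius: float  # px; mean_radius of largest-area member
    centroid: tuple[float, float]  # (row, col) of the largest-area member
    volume_px3: float = math.nan
    volume_um3: float = math.nan

    @property
    def member_keys(self) -> list[tuple[int, int]]:
        return [(m.plane_index, m.label) for m in self.members]


@dataclass
class WellSummary:
    well_id: str
    cyst_count: int
    volumes: list[float]  # um^3
    total_volume: float
    mean_volume: float
    params_fingerprint: str


@dataclass
class GroupSummary:
    group_id: str
    n_wells: int
    mean_count: float
    sem_count: float | None  # None when n_wells < 2
    mean_total_volume: float
    sem_total_volume: float | None
    percent_of_control: float


def _largest_member(members: list[ObjectFeatures]) -> ObjectFeatures:
    # largest area wins; ties broken by the lowest plane index
    return max(members, key=lambda m: (m.area, -m.plane_index))


def _footprints_overlap(a: ObjectFeatures, b: ObjectFeatures) -> bool:
    r0 = max(a.bbox[0], b.bbox[0])
    c0 = max(a.bbox[1], b.bbox[1])
    r1 = min(a.bbox[2], b.bbox[2])
    c1 = min(a.bbox[3], b.bbox[3])
    if r0 >= r1 or c0 >= c1:
        return False
    fa = a.footprint[r0 - a.bbox[0] : r1 - a.bbox[0], c0 - a.bbox[1] : c1 - a.bbox[1]]
    fb = b.footprint[r0 - b.bbox[0] : r1 - b.bbox[0], c0 - b.bbox[1] : c1 - b.bbox[1]]
    return bool(np.any(fa & fb))


def _centroid_inside(a: ObjectFeatures, b: ObjectFeatures) -> bool:
    """True when a's centroid pixel falls inside b's footprint (or vice versa)."""
    for p, q in ((a, b), (b, a)):
        r = int(round(p.centroid[0]))
        c = int(round(p.centroid[1]))
        if q.bbox[0] <= r < q.bbox[2] and q.bbox[1] <= c < q.bbox[3]:
            if q.footprint[r - q.bbox[0], c - q.bbox[1]]:
                return True
    return False


def link_across_planes(
    kept: list[ObjectFeatures], mode: str = "overlap"
) -> list[CystRecord]:
    """Group kept objects into cysts by adjacent-plane co-location.

    Objects in planes ``i`` and ``i + 1`` are linked when their footprints
    share at least one pixel (``mode="overlap"``, default) or when either
    centroid lies inside the other's footprint (``mode="centroid"``).
    Objects in non-adjacent planes are never linked directly, so a one-plane
    gap splits a column of objects into two cysts.  The result is invariant
    to processing direction along z.
    """
    if mode not in ("overlap", "centroid"):
        raise ValueError("mode must be 'overlap' or 'centroid'")
    linked = _footprints_overlap if mode == "overlap" else _centroid_inside

    keys = [(o.plane_index, o.label) for o in kept]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (plane_index, label) keys in input")
    for o in kept:
        if o.footprint is None:
            raise ValueError("link_across_planes requires object footprints")

    # union-find over object indices
    parent = list(range(len(kept)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    by_plane: dict[int, list[int]] = {}
    for idx, o in enumerate(kept):
        by_plane.setdefault(o.plane_index, []).append(idx)
    for p in sorted(by_plane):
        for i in by_plane[p]:
            for j in by_plane.get(p + 1, ()):
                if linked(kept[i], kept[j]):
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri

    groups: dict[int, list[int]] = {}
    for idx in range(len(kept)):
        groups.setdefault(find(idx), []).append(idx)

    records = []
    for idxs in groups.values():
        members = sorted((kept[i] for i in idxs), key=lambda m: m.plane_index)
        big = _largest_member(members)
        records.append(
            CystRecord(
                members=members,
                representative_radius=big.mean_radius,
                centroid=big.centroid,
            )
        )
    # stable output order: by first member's (plane, label)
    records.sort(key=lambda r: r.member_keys[0])
    return records


def estimate_volume(cyst: CystRecord, pixel_size: float) -> CystRecord:
    """Fill in the spherical volume estimate, V = (4/3) * pi * r**3.

    ``r`` is the representative radius in pixels; ``volume_um3`` converts
    through ``pixel_size**3``.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    r = cyst.representative_radius
    v_px3 = (4.0 / 3.0) * math.pi * r**3
    return replace(cyst, volume_px3=v_px3, volume_um3=v_px3 * pixel_size**3)


def params_fingerprint(*param_objects) -> str:
    """Short stable hash of all thresholds/parameters that shaped a result."""
    payload = json.dumps(
        [sorted(vars(p).items()) for p in param_objects], default=str, sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def summarize_well(
    cysts: list[CystRecord], well_id: str, fingerprint: str = ""
) -> WellSummary:
    """Count and volume aggregates for one well (volumes must be populated)."""
    volumes = [c.volume_um3 for c in cysts]
    if any(math.isnan(v) for v in volumes):
        raise ValueError("cyst volumes not populated; run estimate_volume first")
    total = float(sum(volumes))
    return WellSummary(
        well_id=well_id,
        cyst_count=len(cysts),
        volumes=volumes,
        total_volume=total,
        mean_volume=total / len(volumes) if volumes else 0.0,
        params_fingerprint=fingerprint,
    )


def _mean_sem(values: list[float]) -> tuple[float, float | None]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    if arr.size < 2:
        return mean, None
    return mean, float(arr.std(ddof=1) / math.sqrt(arr.size))


def summarize_groups(
    wells: list[WellSummary], design: dict[str, str], control_group: str
) -> list[GroupSummary]:
    """Per-group mean/s.e.m. of cyst count and total volume, vs control.

    ``design`` maps well_id -> group_id; every well must be assigned.
    ``percent_of_control`` scales each group's mean count by the control
    group's mean count.  s.e.m. is sd/sqrt(n) (ddof 1) and is None for
    single-well groups.
    """
    missing = [w.well_id for w in wells if w.well_id not in design]
    if missing:
        raise ValueError(f"wells not assigned to a group: {missing}")
    by_group: dict[str, list[WellSummary]] = {}
    for w in wells:
        by_group.setdefault(design[w.well_id], []).append(w)
    if control_group not in by_group or not by_group[control_group]:
        raise ValueError(f"control group {control_group!r} is empty")
    control_mean = float(np.mean([w.cyst_count for w in by_group[control_group]]))
    if control_mean == 0:
        raise ValueError("control group has zero mean cyst count")
    out = []
    for gid in sorted(by_group):
        ws = by_group[gid]
        mean_c, sem_c = _mean_sem([w.cyst_count for w in ws])
        mean_v, sem_v = _mean_sem([w.total_volume for w in ws])
        out.append(
            GroupSummary(
                group_id=gid,
                n_wells=len(ws),
                mean_count=mean_c,
                sem_count=sem_c,
                mean_total_volume=mean_v,
                sem_total_volume=sem_v,
                percent_of_control=100.0 * mean_c / control_mean,
            )
        )
    return out
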