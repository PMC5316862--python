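"""Reading and writing: TIFF stacks, ground-truth and result tables (TSV).

Stacks are stored as one multi-page TIFF per well (or one file per plane,
named ``well_<id>_z<index>.tif``); tables are tab-separated with a header.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .assembly import CystRecord, GroupSummary, WellSummary
from .features import ObjectFeatures
from .geometry import GroundTruth, ImageStack, SphereSpec, StackGeometry

_FLOAT_FMT = "%.6g"


# ---------------------------------------------------------------------------
# stacks
# ---------------------------------------------------------------------------


def write_stack(stack: ImageStack, path: str | Path, multipage: bool = True) -> list[Path]:
    """Write a stack as a multi-page TIFF (default) or one file per plane.

    With ``multipage=False``, ``path`` is treated as a directory and planes
    are written as ``well_<id>_z<index>.tif``.  Returns the written paths.
    """
    path = Path(path)
    if multipage:
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, stack.planes)
        return [path]
    path.mkdir(parents=True, exist_ok=True)
    out = []
    for i in range(len(stack)):
        p = path / f"well_{stack.well_id}_z{i:02d}.tif"
        tifffile.imwrite(p, stack.planes[i])
        out.append(p)
    return out


def read_stack(path: str | Path, geometry: StackGeometry, well_id: str = "well") -> ImageStack:
    """Read a multi-page TIFF, or a directory of ``*_z<index>.tif`` planes."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*_z*.tif"))
        if not files:
            raise FileNotFoundError(f"no *_z*.tif planes under {path}")
        planes = np.stack([tifffile.imread(f) for f in files])
    else:
        planes = tifffile.imread(path)
        if planes.ndim == 2:
            planes = planes[None]
    return ImageStack(planes=planes, geometry=geometry, well_id=well_id)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    rows = [
        {
            "kind": o.kind,
            "center_x_um": o.center_x,
            "center_y_um": o.center_y,
            "center_z_um": o.center_z,
            "radius_um": o.radius,
            "rim_contrast": o.rim_contrast,
        }
        for o in truth.objects
    ]
    df = pd.DataFrame(
        rows,
        columns=["kind", "center_x_um", "center_y_um", "center_z_um", "radius_um", "rim_contrast"],
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_ground_truth(path: str | Path, geometry: StackGeometry, seed: int = 0) -> GroundTruth:
    df = pd.read_csv(path, sep="\t")
    objects = [
        SphereSpec(
            center_x=row.center_x_um,
            center_y=row.center_y_um,
            center_z=row.center_z_um,
            radius=row.radius_um,
            rim_contrast=row.rim_contrast,
            kind=row.kind,
        )
        for row in df.itertuples()
    ]
    return GroundTruth(geometry=geometry, objects=objects, seed=seed)


# ---------------------------------------------------------------------------
# features, cysts, summaries
# ---------------------------------------------------------------------------


def features_frame(objects: list[ObjectFeatures]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "plane_index": [o.plane_index for o in objects],
            "label": [o.label for o in objects],
            "centroid_row": [o.centroid[0] for o in objects],
            "centroid_col": [o.centroid[1] for o in objects],
            "area_px2": [o.area for o in objects],
            "mean_radius_px": [o.mean_radius for o in objects],
            "radius_cv": [o.radius_cv for o in objects],
            "eccentricity": [o.eccentricity for o in objects],
            "min_row": [o.bbox[0] for o in objects],
            "min_col": [o.bbox[1] for o in objects],
            "max_row": [o.bbox[2] for o in objects],
            "max_col": [o.bbox[3] for o in objects],
        }
    )


def write_features(objects: list[ObjectFeatures], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    features_frame(objects).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def cysts_frame(cysts: list[CystRecord], well_id: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "well": well_id,
            "cyst_id": range(1, len(cysts) + 1),
            "n_members": [len(c.members) for c in cysts],
            "representative_radius_px": [c.representative_radius for c in cysts],
            "volume_um3": [c.volume_um3 for c in cysts],
            "centroid_row": [c.centroid[0] for c in cysts],
            "centroid_col": [c.centroid[1] for c in cysts],
        }
    )


def write_cysts(cysts: list[CystRecord], well_id: str, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cysts_frame(cysts, well_id).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_well_summaries(wells: list[WellSummary], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "well": [w.well_id for w in wells],
            "cyst_count": [w.cyst_count for w in wells],
            "total_volume_um3": [w.total_volume for w in wells],
            "mean_volume_um3": [w.mean_volume for w in wells],
            "params_fingerprint": [w.params_fingerprint for w in wells],
        }
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_group_summaries(groups: list[GroupSummary], path: str | Path) -> None:
    def _fmt(v: float | None) -> float:
        return math.nan if v is None else v

    df = pd.DataFrame(
        {
            "group": [g.group_id for g in groups],
            "n_wells": [g.n_wells for g in groups],
            "mean_count": [g.mean_count for g in groups],
            "sem_count": [_fmt(g.sem_count) for g in groups],
            "mean_total_volume_um3": [g.mean_total_volume for g in groups],
            "sem_total_volume_um3": [_fmt(g.sem_total_volume) for g in groups],
            "percent_of_control": [g.percent_of_control for g in groups],
        }
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read any of the assay TSV tables (counts, Ct, OCR)."""
    return pd.read_csv(path, sep="\t")
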