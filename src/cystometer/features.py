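"""Per-object shape statistics and rule-based filtering.

An object's "radius" is the distribution of Euclidean distances from its
centroid to each of its boundary pixels (pixels with at least one
4-connected background neighbour); the mean and coefficient of variation of
that distribution drive two of the four rejection rules.  Eccentricity uses
the second-central-moments equivalent ellipse (0 for a circle, -> 1 for a
line), matching the usable range of the 0.75 rejection bound.

The four rules, applied per object:

* mean radius <= ``min_mean_radius`` px (debris)            -> reject
* mean radius >  ``max_mean_radius`` px (confluent blobs)   -> reject
* radius CV   >  ``max_radius_cv``      (irregular outline) -> reject
* eccentricity > ``max_eccentricity``   (elongated)         -> reject

All bounds sit exactly as stated: a mean radius of exactly 15 px is
rejected, exactly 200 px is kept; CV exactly 0.2 and eccentricity exactly
0.75 are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import regionprops

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class ObjectFeatures:
    """Shape statistics of one segmented 2D object."""

    plane_index: int
    label: int
    centroid: tuple[float, float]  # (row, col), px
    area: int  # px^2
    mean_radius: float  # px
    radius_cv: float
    eccentricity: float
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col), half-open
    footprint: np.ndarray | None = field(default=None, repr=False)  # bool crop at bbox


@dataclass(frozen=True)
class FilterThresholds:
    min_mean_radius: float = 15.0  # px, exclusive lower bound (<= is rejected)
    max_mean_radius: float = 200.0  # px, inclusive upper bound
    max_radius_cv: float = 0.2  # inclusive
    max_eccentricity: float = 0.75  # inclusive

    def __post_init__(self) -> None:
        if not (0 < self.min_mean_radius < self.max_mean_radius):
            raise ValueError("need 0 < min_mean_radius < max_mean_radius")


#: rejection reason codes, in the order the rules are evaluated
REASON_RADIUS_MIN = "radius_min"
REASON_RADIUS_MAX = "radius_max"
REASON_RADIUS_CV = "radius_cv"
REASON_ECCENTRICITY = "eccentricity"


def compute_features(labels: np.ndarray, plane_index: int = 0) -> list[ObjectFeatures]:
    """Measure every labelled object in a plane.

    Centroid is the unweighted mean of pixel coordinates.  Boundary radii
    are measured to the centres of the object's boundary pixels; pixels on
    the image edge count as boundary.  A single-pixel object has mean
    radius 0, radius CV 0 and eccentricity 0 by convention.
    """
    labels = np.asarray(labels)
    out: list[ObjectFeatures] = []
    for rp in regionprops(labels):
        crop = rp.image
        # inner boundary: object pixels with a 4-connected background
        # neighbour; other labels are never 4-adjacent to this object, so
        # the tight crop (padded implicitly with background) is exact
        interior = ndimage.binary_erosion(crop, structure=_CROSS, border_value=0)
        boundary = crop & ~interior
        br, bc = np.nonzero(boundary)
        min_row, min_col, _, _ = rp.bbox
        cy, cx = rp.centroid
        radii = np.hypot(br + min_row - cy, bc + min_col - cx)
        mean_r = float(radii.mean())
        cv = float(radii.std() / mean_r) if mean_r > 0 else 0.0
        out.append(
            ObjectFeatures(
                plane_index=plane_index,
                label=int(rp.label),
                centroid=(float(cy), float(cx)),
                area=int(rp.area),
                mean_radius=mean_r,
                radius_cv=cv,
                eccentricity=float(rp.eccentricity),
                bbox=tuple(rp.bbox),
                footprint=crop,
            )
        )
    return out


def filter_objects(
    objects: list[ObjectFeatures], thresholds: FilterThresholds | None = None
) -> tuple[list[ObjectFeatures], list[tuple[ObjectFeatures, str]]]:
    """Partition objects into (kept, rejected-with-reason).

    An object is kept iff it passes all four rules; a rejected object is
    tagged with the first rule it violates, in the order radius-min,
    radius-max, radius-CV, eccentricity.
    """
    thresholds = thresholds or FilterThresholds()
    kept: list[ObjectFeatures] = []
    rejected: list[tuple[ObjectFeatures, str]] = []
    for obj in objects:
        if obj.mean_radius <= thresholds.min_mean_radius:
            rejected.append((obj, REASON_RADIUS_MIN))
        elif obj.mean_radius > thresholds.max_mean_radius:
            rejected.append((obj, REASON_RADIUS_MAX))
        elif obj.radius_cv > thresholds.max_radius_cv:
            rejected.append((obj, REASON_RADIUS_CV))
        elif obj.eccentricity > thresholds.max_eccentricity:
            rejected.append((obj, REASON_ECCENTRICITY))
        else:
            kept.append(obj)
    return kept, rejected
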