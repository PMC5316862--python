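"""Stack geometry and ground-truth scene descriptions.

All physical quantities are micrometres; image coordinates are 0-based
(row, col) pixels with the origin at the top-left corner.  Plane ``i`` sits
at depth ``depth_of_first_plane + i * plane_spacing``, increasing down into
the well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Object kinds understood by the phantom renderer.  ``cyst`` is the signal;
#: every other kind is a distractor built to trip exactly one rejection rule.
OBJECT_KINDS = (
    "cyst",
    "debris",
    "oversize_blob",
    "elongated",
    "irregular",
    "border_artifact",
)


@dataclass(frozen=True)
class StackGeometry:
    """Physical geometry of one well's focal-plane stack.

    Defaults match the acquisition protocol the pipeline was designed for:
    28 focal planes 150 um apart, 2448 x 1920 px frames.
    """

    n_planes: int = 28
    plane_spacing: float = 150.0  # um between consecutive focal planes
    width: int = 2448  # px (columns)
    height: int = 1920  # px (rows)
    pixel_size: float = 1.5  # um per px
    depth_of_first_plane: float = 0.0  # um

    def __post_init__(self) -> None:
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")
        if self.plane_spacing <= 0:
            raise ValueError("plane_spacing must be > 0")
        if self.width < 16 or self.height < 16:
            raise ValueError("width and height must be >= 16 px")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def width_um(self) -> float:
        return self.width * self.pixel_size

    @property
    def height_um(self) -> float:
        return self.height * self.pixel_size

    def plane_depths(self) -> np.ndarray:
        """Depth (um) of each focal plane, top plane first."""
        return self.depth_of_first_plane + self.plane_spacing * np.arange(self.n_planes)


@dataclass(frozen=True)
class SphereSpec:
    """One object placed in the well.

    ``center_x`` runs along image columns, ``center_y`` along rows (um);
    ``center_z`` is depth.  ``radius`` is the sphere radius (um) for
    spherical kinds, or the in-plane characteristic radius for the flat
    distractor kinds (``oversize_blob``, ``elongated``, ``irregular``,
    ``border_artifact``), which are rendered only in their nearest plane.
    """

    center_x: float
    center_y: float
    center_z: float
    radius: float
    rim_contrast: float = 0.6
    kind: str = "cyst"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if not (0 < self.rim_contrast <= 1):
            raise ValueError("rim_contrast must lie in (0, 1]")
        if self.kind not in OBJECT_KINDS:
            raise ValueError(f"unknown object kind {self.kind!r}")

    def volume_um3(self) -> float:
        return (4.0 / 3.0) * math.pi * self.radius**3


@dataclass
class GroundTruth:
    """Everything the generator knew: the scene against which recovery is scored."""

    geometry: StackGeometry
    objects: list[SphereSpec]
    seed: int
    noise_sd: float = 0.0
    blur_sigma: float = 0.0

    @property
    def cysts(self) -> list[SphereSpec]:
        return [o for o in self.objects if o.kind == "cyst"]

    @property
    def expected_cyst_count(self) -> int:
        return len(self.cysts)

    @property
    def expected_volumes(self) -> list[float]:
        return [c.volume_um3() for c in self.cysts]


@dataclass
class ImageStack:
    """Ordered focal-plane images of one well.

    ``planes`` is ``(n_planes, height, width)`` uint8 grayscale or
    ``(n_planes, height, width, 3)`` uint8 RGB.
    """

    planes: np.ndarray
    geometry: StackGeometry
    well_id: str = "well"

    def __post_init__(self) -> None:
        p = np.asarray(self.planes)
        if p.ndim not in (3, 4):
            raise ValueError("planes must be (n, h, w) or (n, h, w, 3)")
        n, h, w = p.shape[:3]
        g = self.geometry
        if (n, h, w) != (g.n_planes, g.height, g.width):
            raise ValueError(
                f"planes shape {(n, h, w)} does not match geometry "
                f"{(g.n_planes, g.height, g.width)}"
            )
        self.planes = p

    def __len__(self) -> int:
        return self.planes.shape[0]

    def __getitem__(self, i: int) -> np.ndarray:
        return self.planes[i]
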