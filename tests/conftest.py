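import numpy as np
import pytest

from cystometer import ObjectFeatures, StackGeometry


@pytest.fixture
def scaled_geometry() -> StackGeometry:
    """Full 28-plane stack scaled laterally (612 x 480) for test speed."""
    return StackGeometry(n_planes=28, width=612, height=480, pixel_size=1.5)


@pytest.fixture
def tiny_geometry() -> StackGeometry:
    return StackGeometry(n_planes=8, width=256, height=200, pixel_size=1.5)


def rasterize_disc(radius: float, pad: int = 4) -> np.ndarray:
    """Boolean disc: pixel centres within ``radius`` of the centre."""
    n = int(np.ceil(radius)) + pad
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
    return yy**2 + xx**2 <= radius**2


def rasterize_ellipse(a: float, b: float, pad: int = 4) -> np.ndarray:
    """Boolean axis-aligned ellipse with semi-axes a (cols) and b (rows)."""
    n = int(np.ceil(max(a, b))) + pad
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
    return (xx / a) ** 2 + (yy / b) ** 2 <= 1.0


def obj_from_mask(mask: np.ndarray, plane_index: int, label: int = 1,
                  origin: tuple[int, int] = (0, 0)) -> ObjectFeatures:
    """Build an ObjectFeatures carrying a footprint at a given offset.

    Shape statistics other than the footprint/bbox are filled with
    pass-all-filters placeholder values; linking only looks at footprints.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    r0, c0 = origin
    bbox = (r0 + rows.min(), c0 + cols.min(), r0 + rows.max() + 1, c0 + cols.max() + 1)
    crop = mask[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1]
    return ObjectFeatures(
        plane_index=plane_index,
        label=label,
        centroid=(r0 + rows.mean(), c0 + cols.mean()),
        area=int(mask.sum()),
        mean_radius=30.0,
        radius_cv=0.05,
        eccentricity=0.1,
        bbox=bbox,
        footprint=crop,
    )
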