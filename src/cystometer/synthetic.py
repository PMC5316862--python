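"""Synthetic data with known ground truth.

The phantom generator renders spheres into focal planes the way hollow
Matrigel cysts appear in brightfield: a dark rim around a slightly
brightened lumen on a mid-grey background.  A sphere of radius ``R`` centred
at depth ``z0`` intersects the plane at depth ``z`` iff ``|z - z0| < R``,
with cross-section radius ``sqrt(R**2 - (z - z0)**2)`` (the chord formula).
Rendered planes are Gaussian-blurred, then corrupted with additive Gaussian
noise clipped to the 8-bit range.  Appearance parameters (rim width, lumen
lift, background level) are free knobs of the phantom, not calibrated to any
particular microscope.

Flat distractor kinds (``oversize_blob``, ``elongated``, ``irregular``,
``border_artifact``) are drawn as solid dark shapes in the single plane
nearest their nominal depth; each exists to violate exactly one of the
object-rejection rules.  ``debris`` is a small solid sphere.

The module also generates the assay-side fixtures: negative-binomial miRNA
count tables with planted family-level fold changes, qPCR Ct tables with a
planted polysome displacement, and BOFA-protocol OCR traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import GroundTruth, ImageStack, SphereSpec, StackGeometry

BACKGROUND = 128.0  # mid-grey canvas level (8-bit)
RIM_WIDTH_PX = 3.0  # dark rim thickness
LUMEN_LIFT = 40.0  # lumen brightening at rim_contrast = 1
DEFAULT_NOISE_SD = 1.0
DEFAULT_BLUR_SIGMA = 1.0

#: kinds rendered via the spherical chord formula across planes
_SPHERICAL_KINDS = frozenset({"cyst", "debris"})

_NT = np.array(list("ACGU"))


# ---------------------------------------------------------------------------
# image phantoms
# ---------------------------------------------------------------------------


def _grids(geometry: StackGeometry, spec: SphereSpec, extent_px: float):
    """Bounding-box pixel-coordinate grids around a spec (dy, dx in px)."""
    cx = spec.center_x / geometry.pixel_size
    cy = spec.center_y / geometry.pixel_size
    r0 = max(0, int(math.floor(cy - extent_px)) - 1)
    r1 = min(geometry.height, int(math.ceil(cy + extent_px)) + 2)
    c0 = max(0, int(math.floor(cx - extent_px)) - 1)
    c1 = min(geometry.width, int(math.ceil(cx + extent_px)) + 2)
    if r0 >= r1 or c0 >= c1:
        return None
    rows = np.arange(r0, r1, dtype=float)[:, None]
    cols = np.arange(c0, c1, dtype=float)[None, :]
    return (slice(r0, r1), slice(c0, c1)), rows - cy, cols - cx


def _paint(canvas: np.ndarray, geometry: StackGeometry, spec: SphereSpec, r_px: float) -> None:
    """Draw one object cross-section of in-plane radius ``r_px`` onto ``canvas``."""
    dark = BACKGROUND * (1.0 - spec.rim_contrast)
    kind = spec.kind
    if kind == "elongated":
        extent = 2.0 * r_px  # semi-major axis
    elif kind == "irregular":
        extent = 1.5 * r_px
    elif kind == "border_artifact":
        extent = 3.0 * r_px
    else:
        extent = r_px
    g = _grids(geometry, spec, extent)
    if g is None:
        return
    window, dy, dx = g
    if kind in _SPHERICAL_KINDS:
        d = np.hypot(dy, dx)
        if kind == "cyst":
            lumen = min(255.0, BACKGROUND + LUMEN_LIFT * spec.rim_contrast)
            canvas[window][d <= r_px] = lumen
            canvas[window][(d <= r_px) & (d > r_px - RIM_WIDTH_PX)] = dark
        else:  # debris: small solid dark sphere
            canvas[window][d <= r_px] = dark
    elif kind == "oversize_blob":
        canvas[window][np.hypot(dy, dx) <= r_px] = dark
    elif kind == "elongated":
        # axis ratio 2 ellipse -> analytic eccentricity sqrt(1 - 1/4) = 0.866
        inside = (dx / (2.0 * r_px)) ** 2 + (dy / r_px) ** 2 <= 1.0
        canvas[window][inside] = dark
    elif kind == "irregular":
        # five-lobed polar blob; radius modulation 0.4 gives a boundary-radius
        # CV of roughly 0.28, well past the 0.2 rejection bound
        theta = np.arctan2(dy, dx)
        r_theta = r_px * (1.0 + 0.4 * np.sin(5.0 * theta))
        canvas[window][np.hypot(dy, dx) <= r_theta] = dark
    elif kind == "border_artifact":
        # elongated streak centred on the image edge (axis ratio 3 along y)
        inside = (dx / r_px) ** 2 + (dy / (3.0 * r_px)) ** 2 <= 1.0
        canvas[window][inside] = dark
    else:  # pragma: no cover - kinds are validated by SphereSpec
        raise ValueError(f"unknown kind {kind!r}")


def generate_stack(
    geometry: StackGeometry,
    objects: list[SphereSpec],
    noise_sd: float = DEFAULT_NOISE_SD,
    blur_sigma: float = DEFAULT_BLUR_SIGMA,
    seed: int = 0,
) -> tuple[ImageStack, GroundTruth]:
    """Render a scene of objects into an 8-bit grayscale focal-plane stack.

    Parameters
    ----------
    geometry
        Stack geometry; plane ``i`` lies at depth
        ``depth_of_first_plane + i * plane_spacing``.
    objects
        Scene description.  Objects must lie within the lateral field of
        view (centres inside ``[0, width_um] x [0, height_um]``).
    noise_sd
        Standard deviation of the additive Gaussian noise (8-bit intensity
        units), applied after blurring and clipped to [0, 255].
    blur_sigma
        Gaussian blur (px) applied to the noiseless rendering.
    seed
        Seeds all stochastic draws; identical inputs give bit-identical
        stacks.

    Returns
    -------
    (ImageStack, GroundTruth)
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if blur_sigma < 0:
        raise ValueError("blur_sigma must be >= 0")
    for i, o in enumerate(objects):
        if not (0 <= o.center_x <= geometry.width_um) or not (
            0 <= o.center_y <= geometry.height_um
        ):
            raise ValueError(f"object {i} lies outside the lateral field of view")

    depths = geometry.plane_depths()
    rng = np.random.default_rng(seed)
    planes = np.empty((geometry.n_planes, geometry.height, geometry.width), dtype=np.uint8)

    flat_plane = {}  # object index -> plane index for single-plane kinds
    for i, o in enumerate(objects):
        if o.kind not in _SPHERICAL_KINDS:
            flat_plane[i] = int(np.argmin(np.abs(depths - o.center_z)))

    for p, z in enumerate(depths):
        canvas = np.full((geometry.height, geometry.width), BACKGROUND, dtype=float)
        for i, o in enumerate(objects):
            if o.kind in _SPHERICAL_KINDS:
                dz = z - o.center_z
                if abs(dz) < o.radius:
                    r_px = math.sqrt(o.radius**2 - dz**2) / geometry.pixel_size
                    _paint(canvas, geometry, o, r_px)
            elif flat_plane[i] == p:
                _paint(canvas, geometry, o, o.radius / geometry.pixel_size)
        if blur_sigma > 0:
            canvas = ndimage.gaussian_filter(canvas, blur_sigma, mode="reflect")
        if noise_sd > 0:
            canvas = canvas + rng.normal(0.0, noise_sd, canvas.shape)
        planes[p] = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        geometry=geometry,
        objects=list(objects),
        seed=seed,
        noise_sd=noise_sd,
        blur_sigma=blur_sigma,
    )
    return ImageStack(planes=planes, geometry=geometry), truth


def generate_distractor_suite(geometry: StackGeometry, seed: int = 0) -> list[SphereSpec]:
    """One distractor per rejection rule, placed so none overlaps another.

    Returns debris (mean radius 10 px <= the 15 px minimum), an oversize
    disc (> 200 px), a five-lobed irregular blob (radius CV > 0.2), an
    axis-ratio-2 ellipse (eccentricity 0.866 > 0.75) and an elongated streak
    touching the image edge.  The oversize disc occupies the last focal
    plane on its own; the remaining distractors share the antepenultimate
    plane, so a scene of cysts confined to earlier planes is unaffected.
    """
    ps = geometry.pixel_size
    w_um, h_um = geometry.width_um, geometry.height_um
    depths = geometry.plane_depths()

    oversize_r_px = 210.0
    if min(geometry.width, geometry.height) < 2 * (oversize_r_px + 8):
        raise ValueError(
            "geometry too small to host an oversize (> 200 px radius) distractor"
        )
    small_r_px = 10.0
    elong_r_px = 40.0
    irreg_r_px = 40.0
    border_r_px = 25.0
    for r, needed in ((elong_r_px, 4 * 2), (irreg_r_px, 3 * 2)):
        if min(geometry.width, geometry.height) < r * needed:
            raise ValueError("geometry too small to host the distractor suite")

    z_flat = float(depths[max(0, geometry.n_planes - 3)])
    z_big = float(depths[geometry.n_planes - 1])
    return [
        SphereSpec(0.2 * w_um, 0.25 * h_um, z_flat, small_r_px * ps, 0.8, "debris"),
        SphereSpec(0.5 * w_um, 0.5 * h_um, z_big, oversize_r_px * ps, 0.7, "oversize_blob"),
        SphereSpec(0.75 * w_um, 0.25 * h_um, z_flat, elong_r_px * ps, 0.7, "elongated"),
        SphereSpec(0.3 * w_um, 0.72 * h_um, z_flat, irreg_r_px * ps, 0.7, "irregular"),
        SphereSpec(0.0, 0.65 * h_um, z_flat, border_r_px * ps, 0.7, "border_artifact"),
    ]


def place_spheres(
    geometry: StackGeometry,
    n: int,
    radius_range_um: tuple[float, float] = (45.0, 85.0),
    seed: int = 0,
    margin_px: float = 25.0,
    min_gap_px: float = 30.0,
    plane_range: tuple[int, int] | None = None,
    rim_contrast: float = 0.6,
) -> list[SphereSpec]:
    """Place ``n`` non-overlapping in-band cyst spheres at focal-plane depths.

    Centres sit exactly on plane depths so each sphere's maximal rendered
    cross-section equals its true radius.  Lateral positions are rejection-
    sampled so any two spheres are separated by at least the sum of their
    radii plus ``min_gap_px`` regardless of depth, which guarantees their
    footprints never overlap in adjacent planes.
    """
    lo, hi = radius_range_um
    band_lo = 15.0 * geometry.pixel_size
    band_hi = 200.0 * geometry.pixel_size
    if not (band_lo < lo <= hi <= band_hi):
        raise ValueError(
            f"radius range must lie in the keep band ({band_lo:g}, {band_hi:g}] um"
        )
    if plane_range is None:
        plane_range = (1, max(2, geometry.n_planes - 4))
    rng = np.random.default_rng(seed)
    depths = geometry.plane_depths()
    specs: list[SphereSpec] = []
    margin = margin_px * geometry.pixel_size
    gap = min_gap_px * geometry.pixel_size
    for _ in range(n):
        for _attempt in range(10_000):
            r = float(rng.uniform(lo, hi))
            x = float(rng.uniform(r + margin, geometry.width_um - r - margin))
            y = float(rng.uniform(r + margin, geometry.height_um - r - margin))
            if all(
                math.hypot(x - s.center_x, y - s.center_y) >= r + s.radius + gap
                for s in specs
            ):
                plane = int(rng.integers(plane_range[0], plane_range[1] + 1))
                specs.append(
                    SphereSpec(x, y, float(depths[plane]), r, rim_contrast, "cyst")
                )
                break
        else:
            raise RuntimeError(f"could not place {n} spheres without overlap")
    return specs


# ---------------------------------------------------------------------------
# miRNA expression tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedExpressionModel:
    """Planted family-level differential expression for miRNA count tables.

    ``families`` is a list of ``(family_id, seed_7mer, member_ids,
    planted_log2_fc)``.  Counts follow a negative-binomial mean/dispersion
    parameterisation (variance ``mu + dispersion * mu**2``); dispersion 0
    degenerates to deterministic means so that estimators can be checked for
    exact recovery.
    """

    families: tuple[tuple[str, str, tuple[str, ...], float], ...]
    baseline_counts: float = 500.0
    dispersion: float = 0.0
    n_control: int = 3
    n_disease: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_counts <= 0:
            raise ValueError("baseline_counts must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_control < 1 or self.n_disease < 1:
            raise ValueError("need at least one sample per group")
        seen: set[str] = set()
        for fam_id, seed7, members, _fc in self.families:
            if len(seed7) != 7:
                raise ValueError(f"family {fam_id!r}: seed must be a 7-mer")
            dup = seen.intersection(members)
            if dup:
                raise ValueError(f"member ids shared across families: {sorted(dup)}")
            seen.update(members)


def _random_mature_sequence(rng: np.random.Generator, seed_7mer: str, length: int = 22) -> str:
    """Random mature sequence carrying ``seed_7mer`` at positions 2-8 (1-based)."""
    seq = _NT[rng.integers(0, 4, size=length)]
    seq[1:8] = list(seed_7mer)
    return "".join(seq)


def generate_expression_table(model: PlantedExpressionModel) -> pd.DataFrame:
    """Draw a per-miRNA count table with planted family fold changes.

    Columns: ``mirna_id``, ``mature_sequence``, ``control_1..n``,
    ``disease_1..n``, ``log2_fc`` (from the drawn counts) and
    ``significant`` (True for members of families with a non-zero planted
    fold change).  Deterministic under a fixed model seed.
    """
    rng = np.random.default_rng(model.seed)
    rows = []
    for fam_id, seed7, members, fc in model.families:
        mu_ctrl = model.baseline_counts
        mu_dis = model.baseline_counts * 2.0**fc
        for mid in members:
            seq = _random_mature_sequence(rng, seed7)
            ctrl = _nb_draw(rng, mu_ctrl, model.dispersion, model.n_control)
            dis = _nb_draw(rng, mu_dis, model.dispersion, model.n_disease)
            row = {"mirna_id": mid, "mature_sequence": seq, "family_id": fam_id}
            row.update({f"control_{i + 1}": ctrl[i] for i in range(model.n_control)})
            row.update({f"disease_{i + 1}": dis[i] for i in range(model.n_disease)})
            m_ctrl, m_dis = ctrl.mean(), dis.mean()
            row["log2_fc"] = (
                math.log2(m_dis / m_ctrl) if m_ctrl > 0 and m_dis > 0 else math.nan
            )
            row["significant"] = fc != 0.0
            rows.append(row)
    return pd.DataFrame(rows)


def _nb_draw(rng: np.random.Generator, mu: float, dispersion: float, n: int) -> np.ndarray:
    if dispersion == 0:
        return np.full(n, float(mu))
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p, size=n).astype(float)


# ---------------------------------------------------------------------------
# miPSA Ct tables and OCR traces
# ---------------------------------------------------------------------------


def generate_mipsa_table(
    true_displacement_log2: float,
    reference_shift: float = 0.0,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
    target: str = "miR-17",
    reference: str = "let-7d",
) -> pd.DataFrame:
    """Ct table whose noiseless ddCt displacement equals the planted value.

    The target sits at Ct 20 in control samples and ``20 +
    true_displacement_log2`` in treated samples (a higher Ct means less
    template, i.e. loss from the assayed polysome fraction).
    ``reference_shift`` moves the reference gene's Ct equally in both
    conditions and therefore cancels out of the ddCt.
    """
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    base = {"target": 20.0, "reference": 18.0 + reference_shift}
    rows = []
    for gene_label, gene in (("target", target), ("reference", reference)):
        for condition in ("control", "treated"):
            ct0 = base[gene_label]
            if gene_label == "target" and condition == "treated":
                ct0 = ct0 + true_displacement_log2
            for rep in range(1, n_replicates + 1):
                ct = ct0 + (rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
                rows.append(
                    {
                        "gene": gene,
                        "role": gene_label,
                        "condition": condition,
                        "replicate": rep,
                        "ct": ct,
                    }
                )
    return pd.DataFrame(rows)


def generate_ocr_trace(
    atp_linked: float = 60.0,
    basal_level: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_per_phase: int = 3,
    interval_min: float = 6.5,
) -> pd.DataFrame:
    """BOFA-protocol OCR trace (basal, oligomycin, FCCP, antimycin A/rotenone).

    The post-oligomycin plateau is ``basal_level - atp_linked`` so the
    ATP-linked OCR estimator recovers ``atp_linked`` exactly at zero noise.
    FCCP (maximal) and antimycin/rotenone (non-mitochondrial) plateaus are
    fixed at 1.6x and 0.15x basal.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    levels = {
        "basal": basal_level,
        "oligomycin": basal_level - atp_linked,
        "FCCP": 1.6 * basal_level,
        "antimycinA_rotenone": 0.15 * basal_level,
    }
    rows = []
    t = 0.0
    for phase in ("basal", "oligomycin", "FCCP", "antimycinA_rotenone"):
        for _ in range(n_per_phase):
            ocr = levels[phase] + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append({"time_min": round(t, 2), "phase": phase, "ocr": ocr})
            t += interval_min
    return pd.DataFrame(rows)
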