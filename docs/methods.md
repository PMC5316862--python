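# Methods

## Problem and model

Primary renal epithelial cells cultured in 3D Matrigel form hollow,
fluid-filled spheroids ("cysts").  In brightfield microscopy a cyst
intersected by a focal plane appears as a dark ring (the cell-wall rim)
around a slightly brightened lumen.  A well is imaged as a z-stack:
`n_planes` focal planes a fixed `plane_spacing` apart (defaults 28 planes,
150 um), each a `width x height` frame (defaults 2448 x 1920 px at
1.5 um/px).  Because cysts are often larger than the plane spacing, one
cyst appears in several consecutive planes and must not be counted more
than once.

The pipeline is:

1. **Per-plane segmentation** — grayscale conversion (ITU-R 601 luma),
   optional artifact masking (masked pixels replaced by the median
   unmasked intensity, so they are locally flat and cannot seed
   foreground), absolute high-pass Laplacian, adaptive local-mean
   threshold, then dilation → hole filling → erosion, then connected-
   component labeling.  The chain is edge-driven: the Laplacian responds
   at the rim, thresholding yields a ring, hole filling turns the ring
   into the solid cross-section.
2. **Object statistics and filtering** — for each object: centroid
   (unweighted pixel mean), area, the distribution of centroid-to-boundary
   distances (boundary = object pixels with a 4-connected background
   neighbour), its mean (`mean_radius`) and coefficient of variation
   (`radius_cv`), and moments-ellipse eccentricity.  Objects are rejected
   when `mean_radius <= 15 px`, `mean_radius > 200 px`, `radius_cv > 0.2`,
   or `eccentricity > 0.75`; all bounds are sharp (15 is out, 200 in, 0.2
   in, 0.75 in), and each rejection carries the first violated rule.
3. **Z-deduplication** — objects in *adjacent* planes are linked when
   their pixel footprints overlap by >= 1 px ("same x and y coordinates"
   operationalised robustly; a centroid-containment mode exists).  Cysts
   are connected components of this graph, so the partition is independent
   of processing direction, and a one-plane gap separates cysts.
4. **Volume** — V = (4/3) pi r^3 with r the `mean_radius` of the cyst's
   largest-area cross-section (area ties broken by the lower plane index);
   converted to um^3 via `pixel_size**3`.  Well summaries aggregate counts
   and volumes; group summaries report mean ± s.e.m. (sd/sqrt(n), ddof 1;
   undefined for n = 1) and percent-of-control of the mean count.

## Segmentation parameters

All knobs live in `SegmentationParams` and are config-exposed.  Defaults:
3x3 Laplacian (larger odd sizes switch to a Laplacian of Gaussian with
sigma = size/6), threshold window 51 px, threshold offset 12 intensity
counts, disc structuring element of radius 3, one dilation/erosion
iteration, 8-connectivity.  The offset is set by noise propagation: the
3x3 Laplacian amplifies i.i.d. pixel noise sd by sqrt(20) ≈ 4.5, so at the
phantom's default noise sd of 1 the absolute response in empty regions is
spread over roughly 0–9 counts; 12 clears that band while a blurred rim
step of ~50+ intensity counts still responds at 15–20.  Residual noise
specks that do pass survive morphological closing only as near-pixel-scale
objects and are removed by the 15 px minimum-radius rule.  The threshold
is applied to the Laplacian response by default (`threshold_source`
flag allows thresholding the raw image; `signed_response` keeps the
Laplacian's sign instead of its absolute value).  Borders are handled by
reflection everywhere.

A numerical commitment worth stating: the local mean uses an exact
integral image over the reflect-padded response.  On integer-valued
responses (always the case for 8-bit input through the 3x3 integer
Laplacian) every window sum is exact in float64, so the binarisation is
bit-identical to a literal sliding-window mean — there is no
implementation-dependent tie behaviour at the threshold.

## The phantom generator

`generate_stack` renders known spheres into planes by the chord formula: a
sphere (R, z0) is drawn in the plane at depth z iff |z − z0| < R, as a
dark rim (width 3 px, intensity `background*(1−rim_contrast)`) around a
brightened lumen on a mid-grey (128) background, with cross-section radius
sqrt(R^2 − dz^2)/pixel_size; then Gaussian blur (default sigma 1 px) and
additive Gaussian noise (default sd 1 count) clipped to 8 bits.  One
integer seed drives all draws; identical inputs are bit-identical.
Appearance constants (background 128, rim width 3, lumen lift 40·contrast)
are free knobs of the phantom — the source study does not quantify cyst
appearance — chosen once to give rim contrasts comparable to visible
brightfield rings.

`generate_distractor_suite` supplies one object per rejection rule: a
10 px-radius debris sphere, a >200 px solid disc, an axis-ratio-2 ellipse
(analytic eccentricity 0.866), a five-lobed polar blob (boundary-radius CV
≈ 0.28), and an axis-ratio-3 streak centred on the image edge.  The flat
kinds are rendered only in the plane nearest their depth: rendering an
oversize object as a true sphere would create off-centre cross-sections
back inside the keep band, defeating the rule the object exists to
violate.  The suite occupies late planes so it composes with cyst scenes
placed in earlier planes.

What the phantom does *not* emulate: real optics (PSF, depth-dependent
defocus, refraction through Matrigel), illumination gradients, touching or
nested cysts, debris clouds, or plate-edge meniscus effects.  Passing the
recovery tests therefore shows the operator chain and bookkeeping are
correct under the stated image model, not that the parameter defaults are
optimal for any particular microscope.

## Assay statistics

* **Seed families**: the seed is nucleotides 2–8 (1-based) of the mature
  sequence; identical seeds define a family (T/U normalised; sequences
  < 8 nt flagged unassigned).
* **Cumulative fold change** of a family is log2(sum of member disease
  means / sum of member control means), over either significant-only or
  all expressed members.  This pooled form is the fold change of the
  family treated as one transcript and is well defined for members of
  unequal abundance; a sum-of-log2FC mode exists behind a flag for
  comparison.  Counts are assumed normalised upstream.
* **Pool contribution** is the family's share (%) of summed per-miRNA mean
  counts in a group; over any full partition the shares sum to 100.
* **Cross-model correlation** is the squared Pearson correlation of two
  per-miRNA log2 fold-change vectors over their shared ids (>= 3 required;
  constant vectors yield NaN with a warning).
* **Polysome-shift displacement** (ddCt): dCt = mean Ct(target) − mean
  Ct(reference) per condition; displacement = dCt(treated) − dCt(control),
  in log2 units, positive = target lost from the assayed fraction.  A
  reference shift common to both conditions cancels identically.
* **ATP-linked OCR** = mean basal OCR − mean post-oligomycin OCR; a
  negative value is returned with a warning rather than raised.

The count generator uses a negative-binomial mean/dispersion
parameterisation (variance mu + a·mu^2); dispersion 0 degenerates to
deterministic means, which is what makes exact-recovery tests possible.
Non-integer planted log2 fold changes round-trip through `2**fc`/`log2`
with at most 1 ulp of float error; "exact" recovery is asserted at that
level.

## Problem sizes and tolerances in the tests

End-to-end tests use the full 28-plane geometry scaled laterally to
612 x 480 px (1.5 um/px) with K ∈ {1, 5, 12} planted in-band spheres
(radii 45–85 um placed on plane depths, non-overlapping laterally), with
and without the distractor suite.  Expected behaviour, verified across
seeds: exact count recovery, representative radius within 10% of the true
maximal cross-section (measured ~1.5%), volume within 30% of (4/3) pi R^3
(cubing triples the relative radius error; measured ~5%), zero cysts from
distractor-only scenes.  Oracle-equivalence tests run the adaptive
threshold and labeling against literal sliding-window-mean and BFS
implementations on 200 random <= 64x64 integer images, and the rule filter
against an independent four-predicate check on 10,000 randomized records
including the exact rule boundaries.

## Known limitations

- The original study's artifact-masking criteria are unknown; the pipeline
  accepts a user-supplied mask and makes no claim of reproducing them.
- Whether the original threshold operated on the Laplacian response or the
  raw image is unstated; the response is the default here, with a flag.
- The eccentricity convention (moments ellipse) and the radius-CV
  definition (centroid-to-boundary distances) are the natural readings of
  the stated rules, documented as this package's conventions rather than
  asserted as the original script's.
- Volume assumes sphericity; ellipsoidal cysts are systematically
  mis-estimated, consistently with the original method's assumption.
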