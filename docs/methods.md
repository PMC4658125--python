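# Methods

## Segmentation model

The automatic segmenter assumes multi-specimen scans with a roughly uniform,
light background (drawer floor, slide tray) and specimens that are darker
and texture-rich.  Under that assumption, specimen outlines dominate the
lightness gradient, so the pipeline is:

1. RGB → CIELAB.  Lightness (L, range 0–100) carries the contrast that
   matters; the a/b chroma channels participate in the blur only.  This is a
   deliberate simplification: colour edges that have no lightness contrast
   are invisible to the detector.
2. Separable Gaussian blur per channel, finite kernel of `blur_kernel` px
   (default 5, odd).  When `blur_sigma` is 0 the sigma is derived from the
   kernel as `0.3·((k−1)/2 − 1) + 0.8`, the usual kernel-to-sigma rule for
   small discrete Gaussians.  Border handling is half-sample reflection.
3. 3×3 Sobel derivatives of blurred L in x and y; magnitude √(gₓ²+g_y²).
4. The magnitude is rescaled so its maximum is 255, then thresholded at
   `edge_threshold` (default 40).  Rescaling makes the threshold relative to
   the strongest edge in the scan, so the same default works across scans of
   different contrast; the corollary is that a scan containing *only* faint
   structure will still report its faint edges.  A perfectly uniform image
   has zero gradient everywhere and yields an empty edge map.
5. 8-connected components of the edge map each contribute the bounding
   rectangle of their pixels.  Rectangles below `min_box_fraction` of image
   area (default 1e-5) are discarded as noise.  Rectangles above
   `max_box_fraction` (default 0.5) are *containers*: the component's own
   pixels are removed from its interior and the remainder is re-processed at
   depth − 1 (cap `max_depth`, default 2 — drawer → tray → specimen).  A
   container is replaced by its children when any exist, and components that
   lie wholly inside a recursed container are reported once, as children,
   not twice.  Termination is guaranteed by the depth cap.
6. Output in reading order: boxes are grouped into rows (a box joins the
   current row while its top is within 50% of the row-anchor's height) and
   sorted left-to-right within rows.  A stable order makes CSV rows and
   index-based crop names deterministic.

All parameter values are this package's own hard-coded defaults, exposed as
`SegParams` so a batch configuration can pin or override them.  Whether the
x and y gradients should be thresholded separately or as a combined
magnitude was an open design choice; the combined magnitude was chosen
because it is isotropic.  Overlapping detections are never merged and no
non-maximum suppression is applied — physically overlapping specimens are a
curation problem, not a segmentation problem.

## Sub-segmentation

Within one parent box, the same blurred-lightness gradient magnitude is
flooded with `skimage.segmentation.watershed` from the user's markers.  The
parent's border pixels seed one extra, discarded background basin; without
it, whichever marker's basin reached the background first would engulf the
whole box.  Each marker's basin is bounded, clipped to the parent and
returned as one box; markers must be distinct pixels strictly inside the
parent.  For parents smaller than the blur kernel the kernel shrinks to the
largest odd size that fits.

## Documents, coordinates and persistence

A document is a JSON sidecar (`<scan-stem>.inselect`) holding the scan
path, thumbnail path and width, and the ordered box list.  Box coordinates
are normalized to [0, 1] and quantized to 6 decimal places at construction
time, which makes save → load an exact identity and keeps boxes valid on
both the thumbnail and the full-resolution scan (at 4,096 px the
quantization error is ≈ 0.004 px).  Thumbnails are JPEG quality 85 — fixed
so repeated ingests are byte-stable — and are never upscaled: a source
narrower than the target width is stored as-is.  Crops are cut from the
full-resolution image, clamped to the image boundary (no invented pixels),
rotated clockwise in 90° steps, and written as JPEG quality 95 or TIFF.

## Metadata templates

Templates are YAML: top-level `name`, `thumbnail_width`, `crop_filename`
(ordered field names used to build crop filenames) and a `fields` list of
`{name, mandatory, choices, parser, pattern}`.  Unknown keys — top-level or
per-field — are schema errors, and metadata fields absent from the template
are reported as `unknown-field` violations: in an unattended batch run a
template/document mismatch should fail loudly rather than pass silently.
Parsers: `free-text`, `integer-gt-zero`, `latitude` (decimal in [−90, 90]),
`longitude` ([−180, 180]), `date-ymd` (calendar-valid YYYY-MM-DD), and
`regex`.  Regex matching is anchored to the full string even when the
pattern lacks `^`/`$`, so identifier rules like "exactly nine digits"
cannot be satisfied by a substring.  The built-in `dwc-simple` template
carries the Simple Darwin Core term list, vendored as a plain-text resource
(source URL and transcription date in its header) so builds are offline.

## Synthetic fixtures

The generators produce the two scan layouts the pipeline targets, with
known ground truth and full determinism (integer-coordinate drawing, no
anti-aliasing; the only floating-point step is seeded Gaussian pixel noise,
sd 2 by default on a shade-200 background).

* **Drawers** (default 2400×1800 px, the scale of a drawer thumbnail):
  each specimen is a dark filled ellipse, a 2-px pin and a label-outline
  rectangle in a single shade (drawn 30–90), so its ink is one connected
  region and its edge ring one component whose bounding box is the ground
  truth.  Body widths are drawn uniformly from 36–80 px.  Placement is
  rejection sampling with an exclusion margin of one body width around each
  specimen; an infeasible spec errors out rather than degrading.  Optional
  unit trays are thin nested rectangles (the recursion case); the optional
  distractor is a deterministic rhombus tiling at contrast 10 — enough to
  stress the threshold the way patterned backing paper does, while staying
  below it after rescaling.
* **Slide grids**: six columns × twelve rows of standard-size slides
  (72 sockets) or six × eight for large slides (48), occupancy ⌊f·cols·rows⌋
  by seeded sampling.  A slide is a dark 2-px border, grey glass and a
  full-height label band touching the border, so each slide's edges are one
  connected component.  Empty sockets show a contrast-12 outline that stays
  below the edge threshold.

What the fixtures do **not** model: real specimen texture (legs, wings,
antennae that fragment into multiple edge components), shadows and uneven
illumination, stitching artefacts, parallax, labels detached from their
specimens, and physically overlapping specimens.  Passing the end-to-end
tests therefore shows the pipeline's geometry, bookkeeping and parameter
plumbing are correct on clean, well-separated material — not that recall on
real drawers is 1.0; on real scans the boxes are a refinable approximation,
not a finished count.

## Scorer

Matching is greedy on descending IoU with ties broken by list order,
counting pairs only at IoU ≥ threshold (default 0.5, a parameter because no
single overlap criterion is canonical).  Greedy matching can in principle
return one pair fewer than the maximum matching on adversarial overlap
structures; on disjoint ground truth (the generators guarantee separation)
it is exact, and the tests verify equality with an exhaustive-assignment
oracle on small random instances.

## Problem sizes and determinism

Tests and the acceptance script run on fixture-scale images: 2400×1800
drawers (5–40 specimens, seeds 0–4), a 930×836 slide grid, and ≤ 64×64
arrays for the pixel-exact oracle comparisons (loop convolution, flood
fill, exhaustive matching), which keeps every check at desk scale.  All
randomness flows through `numpy.random.default_rng(seed)`; every pipeline
function is a pure function of its inputs, so identical inputs and
parameters reproduce identical boxes, crops and CSVs byte-for-byte.
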