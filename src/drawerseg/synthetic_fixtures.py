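"""Seeded generators of drawer-like and slide-grid scans, plus a scorer.

These fixtures make the whole pipeline testable without any downloads.
They emulate the two imaging situations a digitization lab produces:

* **Drawers** of pinned specimens — dark elongated bodies with a pin and a
  paper label beneath, on a light drawer floor, optionally grouped into unit
  trays (thin nested rectangles, the "edges-within-edges" case) and
  optionally surrounded by a low-contrast tiling pattern that earlier
  stitching hardware required.
* **Slide grids** — standard microscope slides laid out in a regular grid of
  sockets (six columns by twelve rows for standard slides, six by eight for
  large ones), with a configurable fraction of sockets occupied.

Every generator is a pure function of its spec (the seed included): shapes
are drawn by integer array slicing with no anti-aliasing, so outputs are
bit-identical across platforms.

The scorer matches predicted against ground-truth boxes one-to-one by
descending IoU and reports true/false positives, false negatives, precision
and recall — the bookkeeping a segmentation benchmark needs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage import draw as skdraw

from .errors import ParameterError
from .imaging_io import Box, SourceImage

#: Socket counts of the two slide layouts used for imaging runs.
STANDARD_SLIDE_GRID = (6, 12)  # columns, rows -> 72 sockets
LARGE_SLIDE_GRID = (6, 8)  # columns, rows -> 48 sockets


@dataclasses.dataclass
class DrawerSpec:
    """Parameters of a synthetic drawer scan.

    Defaults approximate a drawer thumbnail: a light floor (shade 200 ± 2
    noise), a dozen specimens with body widths of 36–80 px, no trays and no
    distractor pattern.  ``tray_layout`` is (rows, cols) of unit trays;
    ``distractor`` adds the low-contrast rhombus tiling in empty regions.
    Specimens never overlap: each keeps a clear margin of its own body width.
    """

    width: int = 2400
    height: int = 1800
    n_specimens: int = 12
    specimen_size: tuple[int, int] = (36, 80)
    tray_layout: tuple[int, int] | None = None
    distractor: bool = False
    background: int = 200
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 16 or self.height < 16:
            raise ParameterError("drawer canvas must be at least 16×16 px")
        if self.n_specimens < 0:
            raise ParameterError("n_specimens must be >= 0")
        lo, hi = self.specimen_size
        if not (4 <= lo <= hi):
            raise ParameterError(f"bad specimen_size range: {self.specimen_size}")


@dataclasses.dataclass
class GroundTruth:
    """Normalized rectangles of the placed objects, with labels."""

    boxes: list[tuple[float, float, float, float]]
    labels: list[str] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class SegEval:
    """Matching result of predicted vs ground-truth boxes."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    iou_threshold: float


def iou(a, b) -> float:
    """Intersection over union of two (x0, y0, x1, y1) rectangles."""
    ix0, iy0 = max(a[0], b[0]), max(a[1], b[1])
    ix1, iy1 = min(a[2], b[2]), min(a[3], b[3])
    iw, ih = max(0.0, ix1 - ix0), max(0.0, iy1 - iy0)
    inter = iw * ih
    if inter == 0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


def _rects_of(boxes) -> list[tuple[float, float, float, float]]:
    out = []
    for b in boxes:
        out.append(tuple(b.rect) if isinstance(b, Box) else tuple(b))
    return out


def score_segmentation(pred, truth, iou_threshold: float = 0.5) -> SegEval:
    """Match predictions to ground truth and count TP/FP/FN.

    Greedy one-to-one matching on descending IoU (ties broken by list
    order), counting a pair only when its IoU reaches the threshold.
    Unmatched predictions are false positives; unmatched truths are false
    negatives.
    """
    if not (0.0 < iou_threshold <= 1.0):
        raise ParameterError(f"iou_threshold must be in (0, 1], got {iou_threshold}")
    preds = _rects_of(pred)
    truths = _rects_of(truth.boxes if isinstance(truth, GroundTruth) else truth)

    candidates = []
    for pi, p in enumerate(preds):
        for ti, t in enumerate(truths):
            v = iou(p, t)
            if v >= iou_threshold:
                candidates.append((v, pi, ti))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))

    matched_p: set[int] = set()
    matched_t: set[int] = set()
    tp = 0
    for v, pi, ti in candidates:
        if pi in matched_p or ti in matched_t:
            continue
        matched_p.add(pi)
        matched_t.add(ti)
        tp += 1

    fp = len(preds) - tp
    fn = len(truths) - tp
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 1.0
    return SegEval(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall,
                   iou_threshold=iou_threshold)


# --- drawer generator ------------------------------------------------------


def _draw_rect_outline(canvas, x0, y0, x1, y1, shade, thickness=2) -> None:
    canvas[y0:y0 + thickness, x0:x1] = shade
    canvas[y1 - thickness:y1, x0:x1] = shade
    canvas[y0:y1, x0:x0 + thickness] = shade
    canvas[y0:y1, x1 - thickness:x1] = shade


def _draw_specimen(canvas, x, y, body_w, total_h, shade) -> None:
    """Dark ellipse body + 2-px pin + label outline, all one connected ink."""
    body_h = int(round(total_h * 0.55))
    label_h = int(round(total_h * 0.3))
    cy, cx = y + body_h // 2, x + body_w // 2
    rr, cc = skdraw.ellipse(cy, cx, body_h // 2, body_w // 2, shape=canvas.shape)
    canvas[rr, cc] = shade
    # pin from the body centre down into the label
    label_y0 = y + total_h - label_h
    canvas[cy:label_y0 + 3, cx - 1:cx + 1] = shade
    _draw_rect_outline(canvas, x, label_y0, x + body_w, y + total_h, shade)


def _tiling_pattern(shape, pitch: int, contrast: int, background: int) -> np.ndarray:
    """Deterministic low-contrast rhombus tiling (diagonal line grid)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    lines = ((xx + yy) % pitch < 1) | ((xx - yy) % pitch < 1)
    canvas = np.full(shape, background, dtype=np.int16)
    canvas[lines] = background - contrast
    return canvas


def generate_drawer(spec: DrawerSpec) -> tuple[SourceImage, GroundTruth]:
    """Render a drawer scan and its ground-truth specimen boxes.

    Placement is rejection sampling: each specimen's footprint, inflated by
    its own body width, must not intersect any previously placed footprint
    (and must sit inside its tray when trays are on).  A spec that cannot be
    placed within bounded retries raises a parameter error.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    if spec.distractor:
        canvas = _tiling_pattern((h, w), pitch=40, contrast=10,
                                 background=spec.background)
    else:
        canvas = np.full((h, w), spec.background, dtype=np.int16)

    # tray cells: specimens are assigned round-robin
    cells: list[tuple[int, int, int, int]] = []
    if spec.tray_layout is not None:
        rows, cols = spec.tray_layout
        if rows < 1 or cols < 1:
            raise ParameterError(f"bad tray_layout: {spec.tray_layout}")
        margin = 20
        cell_w = (w - 2 * margin) // cols
        cell_h = (h - 2 * margin) // rows
        for r in range(rows):
            for c in range(cols):
                x0 = margin + c * cell_w
                y0 = margin + r * cell_h
                cells.append((x0 + 8, y0 + 8, x0 + cell_w - 8, y0 + cell_h - 8))
                _draw_rect_outline(canvas, x0 + 8, y0 + 8,
                                   x0 + cell_w - 8, y0 + cell_h - 8, 90)

    placed: list[tuple[int, int, int, int]] = []
    truth: list[tuple[float, float, float, float]] = []
    max_tries = 400 * max(1, spec.n_specimens)
    tries = 0
    lo, hi = spec.specimen_size
    for i in range(spec.n_specimens):
        while True:
            tries += 1
            if tries > max_tries:
                raise ParameterError(
                    f"could not place {spec.n_specimens} specimens on a "
                    f"{w}×{h} canvas after {max_tries} tries"
                )
            body_w = int(rng.integers(lo, hi + 1))
            total_h = int(round(body_w * float(rng.uniform(1.5, 2.0))))
            if cells:
                cx0, cy0, cx1, cy1 = cells[i % len(cells)]
            else:
                cx0, cy0, cx1, cy1 = 10, 10, w - 10, h - 10
            if cx1 - cx0 <= body_w + 2 or cy1 - cy0 <= total_h + 2:
                continue
            x = int(rng.integers(cx0 + 1, cx1 - body_w - 1))
            y = int(rng.integers(cy0 + 1, cy1 - total_h - 1))
            gap = body_w  # one-specimen-width exclusion margin
            inflated = (x - gap, y - gap, x + body_w + gap, y + total_h + gap)
            if any(
                inflated[0] < p[2] and p[0] < inflated[2]
                and inflated[1] < p[3] and p[1] < inflated[3]
                for p in placed
            ):
                continue
            break
        shade = int(rng.integers(30, 90))
        if spec.distractor:
            # clear the tiling beneath the specimen and its margin
            m = 6
            canvas[max(0, y - m):y + total_h + m,
                   max(0, x - m):x + body_w + m] = spec.background
        _draw_specimen(canvas, x, y, body_w, total_h, shade)
        placed.append((x, y, x + body_w, y + total_h))
        truth.append((x / w, y / h, (x + body_w) / w, (y + total_h) / h))

    if spec.noise_sd > 0:
        canvas = canvas + np.round(rng.normal(0.0, spec.noise_sd, size=canvas.shape))
    gray = np.clip(canvas, 0, 255).astype(np.uint8)
    pixels = np.repeat(gray[:, :, None], 3, axis=2)
    labels = [f"specimen-{i + 1}" for i in range(len(truth))]
    return SourceImage(pixels=pixels), GroundTruth(boxes=truth, labels=labels)


# --- slide-grid generator --------------------------------------------------


def generate_slide_grid(
    cols: int = STANDARD_SLIDE_GRID[0],
    rows: int = STANDARD_SLIDE_GRID[1],
    occupancy: float = 1.0,
    seed: int = 0,
    slide_size: tuple[int, int] = (130, 50),
    background: int = 200,
    noise_sd: float = 2.0,
) -> tuple[SourceImage, GroundTruth]:
    """Render a grid of microscope-slide sockets and its ground truth.

    ``floor(occupancy * cols * rows)`` sockets, chosen by seeded sampling,
    hold a slide: a dark border, grey glass, and a full-height label band at
    the left end (so each slide's edges form one connected component).
    Empty sockets show only a faint outline well below the edge threshold.
    Truth boxes are the occupied slide extents.
    """
    if cols < 1 or rows < 1:
        raise ParameterError(f"cols and rows must be >= 1, got {cols}×{rows}")
    if not (0.0 <= occupancy <= 1.0):
        raise ParameterError(f"occupancy must be in [0, 1], got {occupancy}")
    rng = np.random.default_rng(seed)
    slide_w, slide_h = slide_size
    margin = 30
    gap_x, gap_y = 18, 16
    pitch_x, pitch_y = slide_w + gap_x, slide_h + gap_y
    w = 2 * margin + cols * pitch_x - gap_x
    h = 2 * margin + rows * pitch_y - gap_y
    canvas = np.full((h, w), background, dtype=np.int16)

    n_sockets = cols * rows
    n_occupied = int(np.floor(occupancy * n_sockets))
    occupied = set(
        int(i) for i in rng.choice(n_sockets, size=n_occupied, replace=False)
    )

    truth: list[tuple[float, float, float, float]] = []
    labels: list[str] = []
    for idx in range(n_sockets):
        r, c = divmod(idx, cols)
        x0 = margin + c * pitch_x
        y0 = margin + r * pitch_y
        x1, y1 = x0 + slide_w, y0 + slide_h
        if idx not in occupied:
            _draw_rect_outline(canvas, x0, y0, x1, y1, background - 12, thickness=1)
            continue
        canvas[y0:y1, x0:x1] = 150  # glass
        label_w = slide_w // 4
        canvas[y0:y1, x0:x0 + label_w] = 120  # full-height label band
        _draw_rect_outline(canvas, x0, y0, x1, y1, 60, thickness=2)
        truth.append((x0 / w, y0 / h, x1 / w, y1 / h))
        labels.append(f"slide-r{r + 1}c{c + 1}")

    if noise_sd > 0:
        canvas = canvas + np.round(rng.normal(0.0, noise_sd, size=canvas.shape))
    gray = np.clip(canvas, 0, 255).astype(np.uint8)
    pixels = np.repeat(gray[:, :, None], 3, axis=2)
    return SourceImage(pixels=pixels), GroundTruth(boxes=truth, labels=labels)
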