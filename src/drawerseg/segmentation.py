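"""Automatic segmentation and marker-seeded watershed sub-segmentation.

The automatic pipeline converts the thumbnail to CIELAB, blurs each channel
with a finite Gaussian kernel to suppress scanner noise, takes Sobel
derivatives of the lightness channel in x and y, thresholds the gradient
magnitude (rescaled to 0–255) into a binary edge map, and returns the
bounding rectangle of every connected edge component.  Components whose
rectangle covers more than ``max_box_fraction`` of the image are treated as
containers — unit trays inside a drawer — and their interiors are processed
recursively so that edges-within-edges yield the inner specimens rather than
the tray outline.

Sub-segmentation splits a single box containing several touching specimens:
the gradient magnitude inside the box is treated as topography and flooded
from user-supplied markers; each marker's catchment basin becomes one box.

All free parameters live in :class:`SegParams` so a batch configuration can
pin them; both algorithms are pure functions of their inputs.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage as ndi
from skimage import color as skcolor
from skimage import measure as skmeasure
from skimage.segmentation import watershed

from .errors import MetadataLossError, ParameterError
from .imaging_io import Box, Document, SourceImage

SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
SOBEL_Y = SOBEL_X.T


@dataclasses.dataclass
class SegParams:
    """Hard-coded defaults of the segmentation pipeline, exposed for pinning.

    blur_kernel
        Side of the square Gaussian kernel, in pixels; odd and >= 1.
    blur_sigma
        Gaussian sigma in pixels; 0 derives it from the kernel size as
        ``0.3 * ((k - 1) / 2 - 1) + 0.8``.
    edge_threshold
        Threshold on the gradient magnitude after rescaling to [0, 255].
    min_box_fraction / max_box_fraction
        Rectangles below the minimum fraction of image area are discarded as
        noise; rectangles above the maximum are treated as containers.
    max_depth
        Recursion cap for the container rule (drawer -> tray -> specimen).
    """

    blur_kernel: int = 5
    blur_sigma: float = 0.0
    edge_threshold: float = 40.0
    min_box_fraction: float = 1e-5
    max_box_fraction: float = 0.5
    max_depth: int = 2

    def __post_init__(self) -> None:
        if self.blur_kernel < 1 or self.blur_kernel % 2 == 0:
            raise ParameterError(f"blur_kernel must be odd >= 1, got {self.blur_kernel}")
        if not (0.0 <= self.min_box_fraction < self.max_box_fraction <= 1.0):
            raise ParameterError(
                "need 0 <= min_box_fraction < max_box_fraction <= 1, got "
                f"{self.min_box_fraction} and {self.max_box_fraction}"
            )
        if self.max_depth < 1:
            raise ParameterError(f"max_depth must be >= 1, got {self.max_depth}")

    @property
    def sigma(self) -> float:
        if self.blur_sigma > 0:
            return self.blur_sigma
        return 0.3 * ((self.blur_kernel - 1) * 0.5 - 1) + 0.8


@dataclasses.dataclass
class EdgeMap:
    """Binary raster where on-pixels mark edges in the source image."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ParameterError(f"edge mask must be 2-D, got shape {self.mask.shape}")


@dataclasses.dataclass
class Marker:
    """A user-designated seed point ``(x, y)`` in pixel coordinates."""

    point: tuple[int, int]


def _gaussian_kernel1d(size: int, sigma: float) -> np.ndarray:
    r = (size - 1) / 2
    x = np.arange(size, dtype=float) - r
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def _blurred_lightness(pixels: np.ndarray, params: SegParams) -> np.ndarray:
    """CIELAB conversion followed by per-channel separable Gaussian blur.

    Returns the blurred L channel (range 0..100); a and b participate in the
    blur only, documented as a simplification of the colour pipeline.
    """
    lab = skcolor.rgb2lab(pixels)
    if params.blur_kernel > 1:
        kern = _gaussian_kernel1d(params.blur_kernel, params.sigma)
        for axis in (0, 1):
            lab = ndi.convolve1d(lab, kern, axis=axis, mode="reflect")
    return lab[..., 0]


def gradient_magnitude(pixels: np.ndarray, params: SegParams) -> np.ndarray:
    """Sobel gradient magnitude of the blurred lightness channel."""
    L = _blurred_lightness(pixels, params)
    gx = ndi.convolve(L, SOBEL_X, mode="reflect")
    gy = ndi.convolve(L, SOBEL_Y, mode="reflect")
    return np.hypot(gx, gy)


def compute_edge_map(image: SourceImage, params: SegParams | None = None) -> EdgeMap:
    """Binary edge map: thresholded, 0–255-rescaled gradient magnitude."""
    params = params or SegParams()
    h, w = image.height, image.width
    if min(h, w) < max(3, params.blur_kernel):
        raise ParameterError(
            f"image {w}×{h} is smaller than the {params.blur_kernel}-px kernel"
        )
    mag = gradient_magnitude(image.pixels, params)
    peak = mag.max()
    if peak > 0:
        mag = mag * (255.0 / peak)
    mask = mag >= params.edge_threshold
    return EdgeMap(mask=mask)


def _component_rects(mask: np.ndarray) -> list[tuple[tuple[int, int, int, int], np.ndarray, int]]:
    labels = skmeasure.label(mask, connectivity=2)
    out = []
    for region in skmeasure.regionprops(labels):
        y0, x0, y1, x1 = region.bbox
        out.append(((x0, y0, x1, y1), labels, region.label))
    return out


def _contains(outer, inner) -> bool:
    return (outer[0] <= inner[0] and outer[1] <= inner[1]
            and inner[2] <= outer[2] and inner[3] <= outer[3])


def _extract(
    mask: np.ndarray, params: SegParams, depth: int, total_area: int
) -> list[tuple[int, int, int, int]]:
    rects: list[tuple[int, int, int, int]] = []
    plain: list[tuple[int, int, int, int]] = []
    recursed: list[tuple[int, int, int, int]] = []
    for (x0, y0, x1, y1), labels, lab in _component_rects(mask):
        frac = (x1 - x0) * (y1 - y0) / total_area
        if frac < params.min_box_fraction:
            continue
        if frac > params.max_box_fraction and depth > 1:
            # Container (e.g. a unit tray): re-process its interior without
            # the container's own edge pixels, keeping it only when empty.
            sub = mask[y0:y1, x0:x1] & (labels[y0:y1, x0:x1] != lab)
            children = _extract(sub, params, depth - 1, total_area)
            if children:
                recursed.append((x0, y0, x1, y1))
                rects.extend(
                    (cx0 + x0, cy0 + y0, cx1 + x0, cy1 + y0)
                    for cx0, cy0, cx1, cy1 in children
                )
                continue
        plain.append((x0, y0, x1, y1))
    # Components wholly inside a recursed container were already reported as
    # that container's children; emitting them again would duplicate boxes.
    rects.extend(
        r for r in plain if not any(_contains(c, r) for c in recursed)
    )
    return rects


def reading_order(rects: list[tuple]) -> list[tuple]:
    """Sort rectangles row-major: rows grouped at 50% of the row's height."""
    if not rects:
        return []
    ordered = sorted(rects, key=lambda r: (r[1], r[0]))
    rows: list[list] = []
    for r in ordered:
        if rows:
            anchor = rows[-1][0]
            if r[1] < anchor[1] + 0.5 * (anchor[3] - anchor[1]):
                rows[-1].append(r)
                continue
        rows.append([r])
    return [r for row in rows for r in sorted(row, key=lambda r: (r[0], r[1]))]


def extract_boxes(
    edge_map: EdgeMap, params: SegParams | None = None, depth: int | None = None
) -> list[tuple[int, int, int, int]]:
    """Bounding rectangles (half-open pixel coords) of edge components.

    Containers recurse per the area rule; tiny rectangles are discarded; the
    result is in reading order.
    """
    params = params or SegParams()
    depth = params.max_depth if depth is None else depth
    if depth < 1:
        raise ParameterError(f"depth must be >= 1, got {depth}")
    total_area = edge_map.mask.size
    if total_area == 0:
        return []
    return reading_order(_extract(edge_map.mask, params, depth, total_area))


def segment_image(image: SourceImage, params: SegParams | None = None) -> list[Box]:
    """Run the full automatic pipeline on a (thumbnail) image.

    Returns normalized, reading-ordered boxes with rotation 0 and empty
    metadata; deterministic for identical input and parameters.
    """
    params = params or SegParams()
    edge_map = compute_edge_map(image, params)
    rects = extract_boxes(edge_map, params)
    w, h = image.width, image.height
    return [
        Box(rect=(x0 / w, y0 / h, x1 / w, y1 / h))
        for x0, y0, x1, y1 in rects
    ]


def replace_boxes(doc: Document, new_boxes: list[Box], force: bool = False) -> Document:
    """Return a copy of ``doc`` with its boxes replaced.

    Refuses when existing boxes carry metadata unless ``force`` is set, so a
    batch re-segmentation cannot silently destroy keyed-in values.
    """
    has_metadata = any(
        any(v for v in box.fields.values()) for box in doc.boxes
    )
    if has_metadata and not force:
        raise MetadataLossError(
            f"{doc.scan_path}: existing boxes carry metadata; pass force=True to replace"
        )
    return dataclasses.replace(doc, boxes=list(new_boxes))


def _denormalize(rect, width: int, height: int) -> tuple[int, int, int, int]:
    x0 = min(max(int(round(rect[0] * width)), 0), width)
    y0 = min(max(int(round(rect[1] * height)), 0), height)
    x1 = min(max(int(round(rect[2] * width)), 0), width)
    y1 = min(max(int(round(rect[3] * height)), 0), height)
    return x0, y0, x1, y1


def subsegment(
    image: SourceImage,
    parent: Box,
    markers: list[Marker],
    params: SegParams | None = None,
) -> list[Box]:
    """Watershed split of one box: exactly one output box per marker.

    The gradient magnitude inside the parent rectangle is flooded from the
    markers by ascending gradient level; each marker's catchment region is
    bounded, clipped to the parent, and returned as a normalized box that
    contains its marker.
    """
    params = params or SegParams()
    if not markers:
        raise ParameterError("subsegment requires at least one marker")
    w, h = image.width, image.height
    px0, py0, px1, py1 = _denormalize(parent.rect, w, h)
    points = []
    for m in markers:
        mx, my = m.point
        if not (px0 <= mx < px1 and py0 <= my < py1):
            raise ParameterError(
                f"marker {m.point} lies outside parent rectangle "
                f"({px0},{py0})–({px1},{py1})"
            )
        points.append((int(mx), int(my)))
    if len(set(points)) != len(points):
        raise ParameterError("markers must be distinct pixels")

    sub = image.pixels[py0:py1, px0:px1]
    sh, sw = sub.shape[:2]
    # Shrink the kernel for small parents so blur stays well-defined.
    k = min(params.blur_kernel, sw if sw % 2 else sw - 1, sh if sh % 2 else sh - 1)
    k = max(k, 1)
    local = dataclasses.replace(params, blur_kernel=k)
    surface = gradient_magnitude(sub, local)

    # The parent border seeds an implicit background basin (discarded below)
    # so a marker's catchment stops at its specimen instead of flooding the
    # whole box interior.
    seeds = np.zeros((sh, sw), dtype=np.int32)
    background = len(points) + 1
    seeds[0, :] = seeds[-1, :] = background
    seeds[:, 0] = seeds[:, -1] = background
    for i, (mx, my) in enumerate(points, start=1):
        seeds[my - py0, mx - px0] = i
    basins = watershed(surface, markers=seeds)

    boxes = []
    for i in range(1, len(points) + 1):
        ys, xs = np.nonzero(basins == i)
        y0, y1 = int(ys.min()), int(ys.max()) + 1
        x0, x1 = int(xs.min()), int(xs.max()) + 1
        boxes.append(
            Box(
                rect=(
                    (x0 + px0) / w,
                    (y0 + py0) / h,
                    (x1 + px0) / w,
                    (y1 + py0) / h,
                )
            )
        )
    return boxes


# --- pluggable segmenter registry -----------------------------------------
#
# Any callable (image, params) -> list[Box] may be registered under a name
# and used by the batch tools in place of the default pipeline, mirroring a
# plugin design where code modules examine and modify the box list.

_SEGMENTERS: dict[str, object] = {}


def register_segmenter(name: str, fn) -> None:
    _SEGMENTERS[name] = fn


def get_segmenter(name: str = "default"):
    try:
        return _SEGMENTERS[name]
    except KeyError:
        raise ParameterError(
            f"no segmenter {name!r}; registered: {sorted(_SEGMENTERS)}"
        ) from None


register_segmenter("default", segment_image)
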