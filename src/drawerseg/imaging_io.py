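"""Raster I/O, thumbnail generation and document persistence.

A *document* ties together a full-resolution scan, a reduced JPEG thumbnail
on which interactive and algorithmic work happens, and the ordered list of
per-specimen bounding boxes with their metadata.  Documents are persisted as
human-readable JSON sidecars (``<scan-stem>.inselect``) next to the scan, so
a batch run leaves a diff-able audit trail.

Coordinates in a :class:`Box` are normalized to ``[0, 1]`` relative to the
scan, which keeps boxes valid whether they are applied to the thumbnail or
to the full-resolution image; they are converted to 0-based, half-open pixel
rectangles only at the point of use.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import DocumentError, FormatError, InputError, ParameterError

#: Default thumbnail width in pixels when neither the caller nor a template
#: specifies one.
DEFAULT_THUMBNAIL_WIDTH = 4096

#: JPEG quality used for thumbnails; fixed so thumbnail sizes are reproducible.
THUMBNAIL_JPEG_QUALITY = 85

DOCUMENT_SUFFIX = ".inselect"
DOCUMENT_VERSION = 1

#: Normalized coordinates are stored (and therefore held in memory) with this
#: many decimal places, making save/load a strict identity.
COORD_DECIMALS = 6

VALID_ROTATIONS = (0, 90, 180, 270)

#: Raster suffixes recognised when walking directories of scans.
RASTER_SUFFIXES = (".tif", ".tiff", ".png", ".jpg", ".jpeg")


@dataclasses.dataclass
class SourceImage:
    """A decoded 8-bit RGB raster plus the path it came from (if any)."""

    pixels: np.ndarray
    path: Path | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ParameterError(
                f"expected an H×W×3 array, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ParameterError("image must be at least 1×1 pixels")
        if px.dtype != np.uint8:
            raise ParameterError(f"expected uint8 pixels, got {px.dtype}")
        self.pixels = px
        if self.path is not None:
            self.path = Path(self.path)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclasses.dataclass
class Box:
    """One specimen's axis-aligned rectangle in normalized scan coordinates.

    ``rect`` is ``(x0, y0, x1, y1)`` with ``0 <= x0 < x1 <= 1`` and likewise
    for y; ``rotation`` is a clockwise multiple of 90 degrees applied when the
    specimen is cropped; ``fields`` maps metadata field names to string values.
    """

    rect: tuple[float, float, float, float]
    rotation: int = 0
    fields: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.rect) != 4:
            raise ParameterError(f"rect must have 4 elements, got {self.rect!r}")
        x0, y0, x1, y1 = (round(float(v), COORD_DECIMALS) for v in self.rect)
        if not (0.0 <= x0 < x1 <= 1.0):
            raise ParameterError(f"invalid x extent: x0={x0}, x1={x1}")
        if not (0.0 <= y0 < y1 <= 1.0):
            raise ParameterError(f"invalid y extent: y0={y0}, y1={y1}")
        self.rect = (x0, y0, x1, y1)
        if self.rotation not in VALID_ROTATIONS:
            raise ParameterError(
                f"rotation must be one of {VALID_ROTATIONS}, got {self.rotation}"
            )
        self.fields = dict(self.fields)


@dataclasses.dataclass
class Document:
    """The unit of persistence: scan, thumbnail, and ordered boxes."""

    scan_path: str
    thumbnail_path: str | None = None
    thumbnail_width: int = DEFAULT_THUMBNAIL_WIDTH
    boxes: list[Box] = dataclasses.field(default_factory=list)
    template_name: str | None = None

    def document_path(self) -> Path:
        """Sidecar path derived from the scan path."""
        scan = Path(self.scan_path)
        return scan.with_suffix(DOCUMENT_SUFFIX)


@dataclasses.dataclass
class IngestResult:
    """Outcome of :func:`ingest` for one scan."""

    document: Document
    document_path: Path
    skipped: bool


def load_image(path: str | Path) -> SourceImage:
    """Read a raster file (TIFF/JPEG/PNG) into an 8-bit RGB array.

    Grayscale inputs are promoted to three identical channels; alpha is
    dropped.  Raises :class:`InputError` when the file is missing and
    :class:`FormatError` when the bytes cannot be decoded.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"no such image file: {path}")
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            pixels = np.asarray(im, dtype=np.uint8)
    except UnidentifiedImageError as exc:
        raise FormatError(f"cannot decode {path}: {exc}") from exc
    except OSError as exc:
        raise FormatError(f"cannot decode {path}: {exc}") from exc
    return SourceImage(pixels=pixels, path=path)


def save_image(image: SourceImage, path: str | Path, quality: int = 95) -> Path:
    """Write an image; format chosen from the suffix (JPEG/PNG/TIFF)."""
    path = Path(path)
    im = Image.fromarray(image.pixels)
    suffix = path.suffix.lower()
    if suffix in (".jpg", ".jpeg"):
        im.save(path, format="JPEG", quality=quality)
    elif suffix == ".png":
        im.save(path, format="PNG")
    elif suffix in (".tif", ".tiff"):
        im.save(path, format="TIFF")
    else:
        raise ParameterError(f"unsupported image suffix: {path.suffix!r}")
    return path


def make_thumbnail(
    image: SourceImage, target_width: int = DEFAULT_THUMBNAIL_WIDTH
) -> SourceImage:
    """Downscale to ``target_width`` pixels wide, preserving aspect ratio.

    Sources no wider than the target are returned unscaled — a thumbnail is
    by definition lower-resolution, so no upscaling is performed.
    """
    if target_width < 1:
        raise ParameterError(f"target_width must be >= 1, got {target_width}")
    if image.width <= target_width:
        return image
    new_h = max(1, round(image.height * target_width / image.width))
    im = Image.fromarray(image.pixels)
    resized = im.resize((target_width, new_h), resample=Image.Resampling.LANCZOS)
    return SourceImage(pixels=np.asarray(resized, dtype=np.uint8), path=None)


def thumbnail_path_for(scan_path: str | Path) -> Path:
    scan = Path(scan_path)
    return scan.with_name(scan.stem + "_thumbnail.jpg")


def ingest(
    scan_path: str | Path,
    template=None,
    thumbnail_width: int | None = None,
    overwrite: bool = False,
) -> IngestResult:
    """Create an empty document plus thumbnail for a scan.

    The thumbnail width comes from, in order of precedence: the explicit
    ``thumbnail_width`` argument, the template's ``thumbnail_width``, then the
    built-in default of 4096 px.  An existing document is skipped (and
    returned as-is) unless ``overwrite`` is set; the source scan is never
    modified.
    """
    scan_path = Path(scan_path)
    doc_path = scan_path.with_suffix(DOCUMENT_SUFFIX)
    if doc_path.exists() and not overwrite:
        return IngestResult(
            document=load_document(doc_path), document_path=doc_path, skipped=True
        )

    width = thumbnail_width
    if width is None and template is not None:
        width = template.thumbnail_width
    if width is None:
        width = DEFAULT_THUMBNAIL_WIDTH

    image = load_image(scan_path)
    thumb = make_thumbnail(image, width)
    thumb_path = thumbnail_path_for(scan_path)
    save_image(thumb, thumb_path, quality=THUMBNAIL_JPEG_QUALITY)

    doc = Document(
        scan_path=str(scan_path),
        thumbnail_path=str(thumb_path),
        thumbnail_width=width,
        boxes=[],
        template_name=getattr(template, "name", None),
    )
    save_document(doc, doc_path)
    return IngestResult(document=doc, document_path=doc_path, skipped=False)


def save_document(doc: Document, path: str | Path | None = None) -> Path:
    """Serialize a document to its JSON sidecar; returns the path written."""
    path = Path(path) if path is not None else doc.document_path()
    payload = {
        "format": "inselect-document",
        "version": DOCUMENT_VERSION,
        "scan": doc.scan_path,
        "thumbnail": doc.thumbnail_path,
        "thumbnail_width": doc.thumbnail_width,
        "template": doc.template_name,
        "boxes": [
            {
                "rect": [round(v, COORD_DECIMALS) for v in box.rect],
                "rotation": box.rotation,
                "fields": box.fields,
            }
            for box in doc.boxes
        ],
    }
    path.write_text(json.dumps(payload, indent=1, ensure_ascii=False))
    return path


def _require(payload: dict, key: str, types, where: str):
    if key not in payload:
        raise DocumentError(f"{where}: missing key {key!r}")
    value = payload[key]
    if not isinstance(value, types):
        raise DocumentError(f"{where}.{key}: unexpected type {type(value).__name__}")
    return value


def load_document(path: str | Path) -> Document:
    """Parse and validate a JSON sidecar; errors name the offending key."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"no such document: {path}")
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise DocumentError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(payload, dict):
        raise DocumentError(f"{path}: top level must be an object")
    if payload.get("format") != "inselect-document":
        raise DocumentError(f"{path}: format: not an inselect document")

    scan = _require(payload, "scan", str, str(path))
    thumb = payload.get("thumbnail")
    if thumb is not None and not isinstance(thumb, str):
        raise DocumentError(f"{path}.thumbnail: unexpected type")
    width = _require(payload, "thumbnail_width", int, str(path))
    if width < 1:
        raise DocumentError(f"{path}.thumbnail_width: must be >= 1, got {width}")
    template = payload.get("template")
    if template is not None and not isinstance(template, str):
        raise DocumentError(f"{path}.template: unexpected type")

    raw_boxes = _require(payload, "boxes", list, str(path))
    boxes = []
    for i, raw in enumerate(raw_boxes):
        where = f"{path}.boxes[{i}]"
        if not isinstance(raw, dict):
            raise DocumentError(f"{where}: must be an object")
        rect = _require(raw, "rect", list, where)
        rotation = _require(raw, "rotation", int, where)
        fields = _require(raw, "fields", dict, where)
        for k, v in fields.items():
            if not isinstance(k, str) or not isinstance(v, str):
                raise DocumentError(f"{where}.fields: keys and values must be strings")
        try:
            box = Box(rect=tuple(rect), rotation=rotation, fields=fields)
        except ParameterError as exc:
            raise DocumentError(f"{where}.rect: {exc}") from exc
        boxes.append(box)

    return Document(
        scan_path=scan,
        thumbnail_path=thumb,
        thumbnail_width=width,
        boxes=boxes,
        template_name=template,
    )
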