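"""Per-specimen crops at full resolution and CSV metadata export.

Crops are cut from the full-resolution scan (never the thumbnail), with the
box rotation applied; filenames are built from template-selected metadata
values (e.g. the catalog number) with an index fallback, and collisions are
resolved by numeric suffixes.  CSV exports carry one row per box — stem,
index, normalized coordinates to six decimals, rotation, then the metadata
columns — quoted per RFC 4180, UTF-8.
"""

from __future__ import annotations

import csv
import io
import re
from pathlib import Path

import numpy as np

from .errors import GeometryError, ParameterError
from .imaging_io import Box, Document, SourceImage, load_image, save_image
from .metadata_templates import TemplateSpec, validate_box

#: JPEG quality for crops; high because crops are the archival product.
CROP_JPEG_QUALITY = 95

_UNSAFE_RE = re.compile(r"[/\\\s\x00-\x1f]+")

CSV_BASE_COLUMNS = ("scan", "box", "x0", "y0", "x1", "y1", "rotation")


def denormalize_rect(
    rect: tuple[float, float, float, float], width: int, height: int
) -> tuple[int, int, int, int]:
    """Normalized rect -> 0-based half-open pixel rect, clamped to the image."""
    x0 = min(max(round(rect[0] * width), 0), width)
    y0 = min(max(round(rect[1] * height), 0), height)
    x1 = min(max(round(rect[2] * width), 0), width)
    y1 = min(max(round(rect[3] * height), 0), height)
    if x1 - x0 < 1 or y1 - y0 < 1:
        raise GeometryError(
            f"rect {rect} degenerates to {x1 - x0}×{y1 - y0} px at {width}×{height}"
        )
    return x0, y0, x1, y1


def crop_box(source: SourceImage, box: Box) -> SourceImage:
    """Cut a box out of the full-resolution scan and apply its rotation.

    Rotation is clockwise in multiples of 90°; 90 and 270 swap the output
    dimensions.
    """
    x0, y0, x1, y1 = denormalize_rect(box.rect, source.width, source.height)
    crop = source.pixels[y0:y1, x0:x1]
    k = (box.rotation // 90) % 4
    if k:
        crop = np.rot90(crop, k=-k)  # negative k == clockwise
    return SourceImage(pixels=np.ascontiguousarray(crop), path=None)


def sanitize_filename(stem: str) -> str:
    """Replace path separators, whitespace and control characters with '-'."""
    return _UNSAFE_RE.sub("-", stem)


def crop_filename(
    box: Box,
    index: int,
    template: TemplateSpec | None = None,
    extension: str = ".jpg",
) -> str:
    """Build a crop filename from template-selected metadata values.

    Joins the values of the template's ``crop_filename`` fields with '_';
    falls back to the zero-padded 1-based index when no pattern is available
    or any pattern field is empty.
    """
    pattern = template.crop_filename if template is not None else ()
    values = [box.fields.get(name, "") for name in pattern]
    if values and all(values):
        stem = "_".join(values)
    else:
        stem = f"{index:04d}"
    return sanitize_filename(stem) + extension


def export_crops(
    doc: Document,
    out_dir: str | Path,
    template: TemplateSpec | None = None,
    image_format: str = "jpg",
    quality: int = CROP_JPEG_QUALITY,
) -> list[Path]:
    """Write one cropped image per box, in document box order.

    The full-resolution scan is loaded once per document.  Filename
    collisions get '-1', '-2', … suffixes so no crop ever overwrites another.
    """
    if image_format not in ("jpg", "tiff"):
        raise ParameterError(f"image_format must be 'jpg' or 'tiff', got {image_format!r}")
    extension = ".jpg" if image_format == "jpg" else ".tif"
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if not doc.boxes:
        return []
    source = load_image(doc.scan_path)
    written: list[Path] = []
    used: set[str] = set()
    for i, box in enumerate(doc.boxes, start=1):
        name = crop_filename(box, i, template, extension)
        if name in used:
            stem = name[: -len(extension)]
            n = 1
            while f"{stem}-{n}{extension}" in used:
                n += 1
            name = f"{stem}-{n}{extension}"
        used.add(name)
        crop = crop_box(source, box)
        path = out_dir / name
        save_image(crop, path, quality=quality)
        written.append(path)
    return written


def _field_columns(doc: Document, template: TemplateSpec | None) -> list[str]:
    if template is not None:
        return [f.name for f in template.fields]
    seen: list[str] = []
    for box in doc.boxes:
        for name in box.fields:
            if name not in seen:
                seen.append(name)
    return seen


def export_csv(
    doc: Document,
    template: TemplateSpec | None = None,
    include_validity: bool = False,
) -> str:
    """Render a document's metadata as CSV text (one row per box).

    Columns: scan stem, 1-based box index, normalized x0,y0,x1,y1 to six
    decimals, rotation, then the template's fields (or the union of observed
    field names in first-appearance order when no template is given).  With
    ``include_validity`` a final 'valid' column records whether the box
    passes template validation.
    """
    columns = list(CSV_BASE_COLUMNS) + _field_columns(doc, template)
    if include_validity:
        if template is None:
            raise ParameterError("include_validity requires a template")
        columns.append("valid")
    stem = Path(doc.scan_path).stem

    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\r\n")
    writer.writerow(columns)
    for i, box in enumerate(doc.boxes, start=1):
        row = [stem, str(i)]
        row.extend(f"{v:.6f}" for v in box.rect)
        row.append(str(box.rotation))
        row.extend(box.fields.get(name, "") for name in columns[7:] if name != "valid")
        if include_validity:
            row.append(str(validate_box(box.fields, template).ok))
        writer.writerow(row)
    return buf.getvalue()


def write_csv(
    doc: Document,
    path: str | Path | None = None,
    template: TemplateSpec | None = None,
    include_validity: bool = False,
) -> Path:
    """Write the document's CSV next to the scan (``<scan-stem>.csv``)."""
    if path is None:
        scan = Path(doc.scan_path)
        path = scan.with_suffix(".csv")
    path = Path(path)
    path.write_text(export_csv(doc, template, include_validity), encoding="utf-8", newline="")
    return path
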