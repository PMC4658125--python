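"""Metadata templates: YAML parsing, field validation, built-in Darwin Core.

A template (`.inselect_template` file) declares the metadata fields that
every specimen box must carry, whether each is mandatory, an optional
drop-down choice list, and a value parser.  Parsers cover the validations a
digitization workflow needs — an integer greater than zero, a latitude, a
longitude, a calendar date in YYYY-MM-DD form — plus arbitrary regular
expressions for institution-specific identifiers such as a nine-digit
catalog number.  Regex matching is anchored to the full string even when the
pattern lacks anchors, so stray whitespace can never sneak through.

Validation never raises: it returns violation *values*, which batch tooling
aggregates into per-box reports.
"""

from __future__ import annotations

import dataclasses
import datetime
import re
from importlib import resources
from pathlib import Path
from typing import NamedTuple

import yaml

from .errors import (
    TemplateParseError,
    TemplatePatternError,
    TemplateSchemaError,
)

MISSING_MANDATORY = "missing-mandatory"
NOT_IN_CHOICES = "not-in-choices"
PARSE_FAILURE = "parse-failure"
UNKNOWN_FIELD = "unknown-field"

FREE_TEXT = "free-text"
PARSER_NAMES = (
    FREE_TEXT,
    "integer-gt-zero",
    "latitude",
    "longitude",
    "date-ymd",
    "regex",
)

#: Reserved name of the built-in Simple Darwin Core template.
DWC_TEMPLATE_NAME = "dwc-simple"

_DECIMAL_RE = re.compile(r"[+-]?\d+(\.\d+)?")
_INTEGER_RE = re.compile(r"[+-]?\d+")
_DATE_RE = re.compile(r"\d{4}-\d{2}-\d{2}")


class Violation(NamedTuple):
    field: str
    reason: str


@dataclasses.dataclass(frozen=True)
class FieldSpec:
    """One metadata field: name, mandatory flag, choices and value parser."""

    name: str
    mandatory: bool = False
    choices: tuple[str, ...] | None = None
    parser: str = FREE_TEXT
    pattern: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise TemplateSchemaError("field name must be non-empty")
        if self.parser not in PARSER_NAMES:
            raise TemplateSchemaError(
                f"field {self.name!r}: unknown parser {self.parser!r}"
            )
        if self.parser == "regex":
            if not self.pattern:
                raise TemplatePatternError(
                    f"field {self.name!r}: parser 'regex' requires a pattern"
                )
            try:
                re.compile(self.pattern)
            except re.error as exc:
                raise TemplatePatternError(
                    f"field {self.name!r}: bad pattern {self.pattern!r}: {exc}"
                ) from exc
        elif self.pattern is not None:
            raise TemplatePatternError(
                f"field {self.name!r}: pattern given but parser is {self.parser!r}"
            )


@dataclasses.dataclass(frozen=True)
class TemplateSpec:
    """A parsed metadata template."""

    name: str
    fields: tuple[FieldSpec, ...]
    thumbnail_width: int = 4096
    crop_filename: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise TemplateSchemaError("template name must be non-empty")
        if not self.fields:
            raise TemplateSchemaError("template must declare at least one field")
        names = [f.name for f in self.fields]
        if len(set(names)) != len(names):
            raise TemplateSchemaError(f"duplicate field names in {self.name!r}")
        if self.thumbnail_width < 1:
            raise TemplateSchemaError(
                f"thumbnail_width must be >= 1, got {self.thumbnail_width}"
            )
        unknown = [n for n in self.crop_filename if n not in names]
        if unknown:
            raise TemplateSchemaError(
                f"crop_filename names unknown fields: {unknown}"
            )

    def field(self, name: str) -> FieldSpec:
        for f in self.fields:
            if f.name == name:
                return f
        raise KeyError(name)


@dataclasses.dataclass(frozen=True)
class ValidationReport:
    violations: tuple[Violation, ...]

    @property
    def ok(self) -> bool:
        return not self.violations


_TOP_KEYS = {"name", "thumbnail_width", "crop_filename", "fields"}
_FIELD_KEYS = {"name", "mandatory", "choices", "parser", "pattern"}


def parse_template(text: str) -> TemplateSpec:
    """Parse `.inselect_template` YAML text; unknown keys are rejected."""
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise TemplateParseError(f"not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise TemplateSchemaError("template must be a YAML mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise TemplateSchemaError(f"unknown top-level keys: {sorted(unknown)}")
    if "name" not in raw:
        raise TemplateSchemaError("missing 'name'")
    if "fields" not in raw or not isinstance(raw["fields"], list):
        raise TemplateSchemaError("missing or malformed 'fields' list")

    fields = []
    for i, f in enumerate(raw["fields"]):
        if not isinstance(f, dict):
            raise TemplateSchemaError(f"fields[{i}]: must be a mapping")
        extra = set(f) - _FIELD_KEYS
        if extra:
            raise TemplateSchemaError(f"fields[{i}]: unknown keys {sorted(extra)}")
        if "name" not in f:
            raise TemplateSchemaError(f"fields[{i}]: missing 'name'")
        choices = f.get("choices")
        if choices is not None:
            if not isinstance(choices, list):
                raise TemplateSchemaError(f"fields[{i}]: 'choices' must be a list")
            choices = tuple(str(c) for c in choices)
        fields.append(
            FieldSpec(
                name=str(f["name"]),
                mandatory=bool(f.get("mandatory", False)),
                choices=choices,
                parser=str(f.get("parser", FREE_TEXT)),
                pattern=f.get("pattern"),
            )
        )

    crop = raw.get("crop_filename", [])
    if isinstance(crop, str):
        crop = [crop]
    if not isinstance(crop, list):
        raise TemplateSchemaError("'crop_filename' must be a list of field names")

    return TemplateSpec(
        name=str(raw["name"]),
        fields=tuple(fields),
        thumbnail_width=int(raw.get("thumbnail_width", 4096)),
        crop_filename=tuple(str(c) for c in crop),
    )


def render_template(spec: TemplateSpec) -> str:
    """Serialize a template back to YAML; inverse of :func:`parse_template`."""
    raw: dict = {"name": spec.name, "thumbnail_width": spec.thumbnail_width}
    if spec.crop_filename:
        raw["crop_filename"] = list(spec.crop_filename)
    raw["fields"] = []
    for f in spec.fields:
        entry: dict = {"name": f.name, "mandatory": f.mandatory, "parser": f.parser}
        if f.choices is not None:
            entry["choices"] = list(f.choices)
        if f.pattern is not None:
            entry["pattern"] = f.pattern
        raw["fields"].append(entry)
    return yaml.safe_dump(raw, sort_keys=False, allow_unicode=True)


def load_template(path: str | Path) -> TemplateSpec:
    return parse_template(Path(path).read_text())


# --- value parsers ---------------------------------------------------------


def _parse_integer_gt_zero(value: str) -> bool:
    return bool(_INTEGER_RE.fullmatch(value)) and int(value) > 0


def _parse_decimal_in(value: str, lo: float, hi: float) -> bool:
    if not _DECIMAL_RE.fullmatch(value):
        return False
    return lo <= float(value) <= hi


def _parse_date_ymd(value: str) -> bool:
    if not _DATE_RE.fullmatch(value):
        return False
    try:
        datetime.date.fromisoformat(value)
    except ValueError:
        return False
    return True


_PARSERS = {
    FREE_TEXT: lambda v: True,
    "integer-gt-zero": _parse_integer_gt_zero,
    "latitude": lambda v: _parse_decimal_in(v, -90.0, 90.0),
    "longitude": lambda v: _parse_decimal_in(v, -180.0, 180.0),
    "date-ymd": _parse_date_ymd,
}


def validate_value(value: str | None, field: FieldSpec) -> str | None:
    """Check one value against one field; returns a violation reason or None.

    Empty values are only a problem for mandatory fields; non-empty values
    must be in the choice list when one is set, else satisfy the parser.
    """
    value = "" if value is None else value
    if value == "":
        return MISSING_MANDATORY if field.mandatory else None
    if field.choices is not None:
        return None if value in field.choices else NOT_IN_CHOICES
    if field.parser == "regex":
        return None if re.fullmatch(field.pattern, value) else PARSE_FAILURE
    return None if _PARSERS[field.parser](value) else PARSE_FAILURE


def validate_box(fields: dict[str, str], template: TemplateSpec) -> ValidationReport:
    """Validate a box's field map against every template field.

    Fields present in the map but absent from the template are reported as
    ``unknown-field`` — a template/document mismatch in a batch run should be
    loud, not silent.
    """
    violations = []
    for f in template.fields:
        reason = validate_value(fields.get(f.name), f)
        if reason is not None:
            violations.append(Violation(f.name, reason))
    known = {f.name for f in template.fields}
    for name in fields:
        if name not in known:
            violations.append(Violation(name, UNKNOWN_FIELD))
    return ValidationReport(violations=tuple(violations))


def darwin_core_terms() -> tuple[str, ...]:
    """Names of the Simple Darwin Core terms, from the vendored resource."""
    text = resources.files("drawerseg.data").joinpath("darwin_core_simple_terms.txt").read_text()
    return tuple(
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


def default_darwin_core_template() -> TemplateSpec:
    """The built-in template with every Simple Darwin Core term, all optional."""
    fields = tuple(FieldSpec(name=t) for t in darwin_core_terms())
    return TemplateSpec(
        name=DWC_TEMPLATE_NAME,
        fields=fields,
        crop_filename=("catalogNumber",),
    )


def get_template(name_or_path: str | Path) -> TemplateSpec:
    """Resolve the reserved built-in name or load a template file."""
    if str(name_or_path) == DWC_TEMPLATE_NAME:
        return default_darwin_core_template()
    return load_template(name_or_path)
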