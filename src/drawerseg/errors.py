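"""Exception hierarchy shared across the package."""


class DrawersegError(Exception):
    """Base class for all package errors."""


class InputError(DrawersegError):
    """A required input file is missing or unreadable."""


class FormatError(DrawersegError):
    """Bytes that should be a decodable raster are not."""


class ParameterError(DrawersegError):
    """A caller-supplied parameter violates its contract."""


class GeometryError(DrawersegError):
    """A rectangle degenerates to fewer than one pixel."""


class DocumentError(DrawersegError):
    """A document sidecar is schema-invalid; message names the offending key."""


class MetadataLossError(DrawersegError):
    """Replacing boxes would silently discard user-entered metadata."""


class TemplateError(DrawersegError):
    """Base class for metadata-template problems."""


class TemplateParseError(TemplateError):
    """Template text is not valid YAML."""


class TemplateSchemaError(TemplateError):
    """Template YAML is well-formed but violates the template schema."""


class TemplatePatternError(TemplateError):
    """A regex-validated field has a missing or uncompilable pattern."""
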