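"""Template parsing, field validation and the built-in Darwin Core template."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from drawerseg.errors import (
    TemplateParseError,
    TemplatePatternError,
    TemplateSchemaError,
)
from drawerseg.metadata_templates import (
    MISSING_MANDATORY,
    NOT_IN_CHOICES,
    PARSE_FAILURE,
    UNKNOWN_FIELD,
    FieldSpec,
    TemplateSpec,
    default_darwin_core_template,
    get_template,
    parse_template,
    render_template,
    validate_box,
    validate_value,
)

HYMENOPTERA_YAML = """\
name: Hymenoptera
thumbnail_width: 4096
crop_filename: [Catalog number]
fields:
  - name: Catalog number
    mandatory: true
    parser: regex
    pattern: '^[0-9]{9}$'
  - name: Location
    mandatory: true
    choices: [Gallery 1, Darwin Centre 1, Darwin Centre 2]
  - name: Family
    mandatory: true
    choices: [Apidae, Formicidae, Vespidae]
  - name: Subfamily
    mandatory: true
    choices: [Apinae, Myrmicinae, Vespinae]
"""


class TestParseTemplate:
    def test_hymenoptera_template(self):
        spec = parse_template(HYMENOPTERA_YAML)
        assert spec.name == "Hymenoptera"
        assert len(spec.fields) == 4
        assert all(f.mandatory for f in spec.fields)
        assert spec.field("Catalog number").parser == "regex"
        assert spec.field("Location").choices == (
            "Gallery 1", "Darwin Centre 1", "Darwin Centre 2"
        )

    def test_thumbnail_width_carried(self):
        spec = parse_template("name: t\nthumbnail_width: 2048\nfields:\n  - name: a\n")
        assert spec.thumbnail_width == 2048

    def test_regex_parser_without_pattern_rejected(self):
        with pytest.raises(TemplatePatternError):
            parse_template("name: t\nfields:\n  - name: a\n    parser: regex\n")

    def test_unknown_top_level_key_rejected(self):
        with pytest.raises(TemplateSchemaError, match="surprise"):
            parse_template("name: t\nsurprise: 1\nfields:\n  - name: a\n")

    def test_malformed_yaml_rejected(self):
        with pytest.raises(TemplateParseError):
            parse_template("name: [unclosed")

    @pytest.mark.parametrize("text", ["fields:\n  - name: a\n", "name: t\n"])
    def test_missing_name_or_fields_rejected(self, text):
        with pytest.raises(TemplateSchemaError):
            parse_template(text)

    def test_bad_regex_names_field(self):
        bad = "name: t\nfields:\n  - name: code\n    parser: regex\n    pattern: '['\n"
        with pytest.raises(TemplatePatternError, match="code"):
            parse_template(bad)

    def test_duplicate_field_names_rejected(self):
        with pytest.raises(TemplateSchemaError):
            parse_template("name: t\nfields:\n  - name: a\n  - name: a\n")


_field_names = st.lists(
    st.text("abcdefg", min_size=1, max_size=5), min_size=1, max_size=4, unique=True
)


@st.composite
def template_specs(draw):
    names = draw(_field_names)
    fields = []
    for name in names:
        parser = draw(st.sampled_from(
            ["free-text", "integer-gt-zero", "latitude", "longitude", "date-ymd", "regex"]
        ))
        pattern = draw(st.sampled_from(["[0-9]{9}", "[a-z]+", "x.*"])) if parser == "regex" else None
        choices = None
        if parser == "free-text" and draw(st.booleans()):
            choices = tuple(draw(st.lists(st.text("pqr", min_size=1, max_size=3),
                                          min_size=1, max_size=3, unique=True)))
        fields.append(FieldSpec(
            name=name,
            mandatory=draw(st.booleans()),
            choices=choices,
            parser=parser,
            pattern=pattern,
        ))
    return TemplateSpec(
        name=draw(st.text("abc", min_size=1, max_size=6)),
        fields=tuple(fields),
        thumbnail_width=draw(st.integers(1, 8192)),
        crop_filename=tuple(draw(st.lists(st.sampled_from(names), max_size=2, unique=True))),
    )


class TestRenderRoundTrip:
    @given(spec=template_specs())
    def test_parse_render_is_identity(self, spec):
        assert parse_template(render_template(spec)) == spec


def _days_in_month(year, month):
    """Independent calendar oracle via explicit day-count table."""
    table = [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]
    leap = year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)
    return 29 if (month == 2 and leap) else table[month - 1]


class TestValidateValue:
    CATALOG = FieldSpec(name="Catalog number", mandatory=True,
                        parser="regex", pattern="^[0-9]{9}$")

    @pytest.mark.parametrize("value,expected", [
        ("012345678", None),
        ("A12345678", PARSE_FAILURE),
        ("12345678", PARSE_FAILURE),        # eight digits
        ("0123456789", PARSE_FAILURE),      # ten digits
        (" 012345678", PARSE_FAILURE),      # leading whitespace
        ("012345678 ", PARSE_FAILURE),      # trailing whitespace
        ("", MISSING_MANDATORY),
        (None, MISSING_MANDATORY),
    ])
    def test_nine_digit_catalog_number(self, value, expected):
        assert validate_value(value, self.CATALOG) == expected

    def test_unanchored_pattern_still_full_string(self):
        field = FieldSpec(name="c", parser="regex", pattern="[0-9]{3}")
        assert validate_value("123", field) is None
        assert validate_value("1234", field) == PARSE_FAILURE
        assert validate_value("a123", field) == PARSE_FAILURE

    @pytest.mark.parametrize("value,expected", [
        ("-90", None), ("90", None), ("89.9999", None), ("-45.5", None),
        ("91.0", PARSE_FAILURE), ("-90.0001", PARSE_FAILURE),
        ("abc", PARSE_FAILURE), ("1e2", PARSE_FAILURE), ("nan", PARSE_FAILURE),
    ])
    def test_latitude(self, value, expected):
        assert validate_value(value, FieldSpec(name="lat", parser="latitude")) == expected

    @pytest.mark.parametrize("value,expected", [
        ("-180", None), ("180", None), ("179.5", None),
        ("180.5", PARSE_FAILURE), ("-181", PARSE_FAILURE),
    ])
    def test_longitude(self, value, expected):
        assert validate_value(value, FieldSpec(name="lon", parser="longitude")) == expected

    @pytest.mark.parametrize("value,expected", [
        ("1", None), ("42", None), ("0", PARSE_FAILURE), ("-3", PARSE_FAILURE),
        ("3.5", PARSE_FAILURE), ("x", PARSE_FAILURE), ("1 ", PARSE_FAILURE),
    ])
    def test_integer_greater_than_zero(self, value, expected):
        assert validate_value(value, FieldSpec(name="n", parser="integer-gt-zero")) == expected

    def test_dates_against_day_count_oracle(self):
        field = FieldSpec(name="d", parser="date-ymd")
        for year in (1900, 1999, 2000, 2015, 2016):
            for month in range(1, 13):
                for day in range(1, 33):
                    value = f"{year:04d}-{month:02d}-{day:02d}"
                    expected = None if day <= _days_in_month(year, month) else PARSE_FAILURE
                    assert validate_value(value, field) == expected, value

    @pytest.mark.parametrize("value", ["2015-13-01", "2015-00-10", "2015-1-1",
                                       "15-01-01", "2015/01/01"])
    def test_malformed_dates_rejected(self, value):
        assert validate_value(value, FieldSpec(name="d", parser="date-ymd")) == PARSE_FAILURE

    def test_choices(self):
        field = FieldSpec(name="Family", choices=("Apidae", "Formicidae"))
        assert validate_value("Apidae", field) is None
        assert validate_value("Vespidae", field) == NOT_IN_CHOICES

    def test_exhaustive_small_alphabet_integer_parser(self):
        """Every string of length <= 3 over {'0','1','a','-'}: accepted iff
        it is all digits with value > 0 (checked by an independent predicate)."""
        field = FieldSpec(name="n", parser="integer-gt-zero")
        alphabet = "01a-"
        for length in range(4):
            for chars in itertools.product(alphabet, repeat=length):
                s = "".join(chars)
                body = s[1:] if s[:1] in "+-" else s
                ok = s == "" or (  # empty value on an optional field is fine
                    len(body) > 0
                    and all(c in "0123456789" for c in body)
                    and not s.startswith("-")  # negative can never exceed zero
                    and int(body) > 0
                )
                got = validate_value(s, field)
                assert (got is None) == ok, s


class TestValidateBox:
    spec = parse_template(HYMENOPTERA_YAML)
    VALID = {
        "Catalog number": "013244667",
        "Location": "Gallery 1",
        "Family": "Apidae",
        "Subfamily": "Apinae",
    }

    def test_all_fields_valid(self):
        report = validate_box(self.VALID, self.spec)
        assert report.ok and report.violations == ()

    def test_missing_catalog_number(self):
        fields = dict(self.VALID)
        del fields["Catalog number"]
        report = validate_box(fields, self.spec)
        assert not report.ok
        assert report.violations == (("Catalog number", MISSING_MANDATORY),)

    def test_unknown_field_reported(self):
        fields = dict(self.VALID, barcode="x")
        report = validate_box(fields, self.spec)
        assert ("barcode", UNKNOWN_FIELD) in report.violations

    def test_no_mandatory_fields_and_empty_metadata_is_ok(self):
        spec = TemplateSpec(name="t", fields=(FieldSpec(name="note"),))
        assert validate_box({}, spec).ok

    @given(fields=st.dictionaries(
        st.sampled_from(["Catalog number", "Location", "Family", "Subfamily", "other"]),
        st.sampled_from(["", "013244667", "Gallery 1", "Apidae", "Apinae", "zzz"]),
        max_size=5,
    ))
    def test_ok_iff_no_violations(self, fields):
        report = validate_box(fields, self.spec)
        assert report.ok == (len(report.violations) == 0)


class TestDarwinCoreTemplate:
    def test_contains_catalog_number(self):
        spec = default_darwin_core_template()
        assert any(f.name == "catalogNumber" for f in spec.fields)

    def test_no_field_mandatory_all_free_text(self):
        spec = default_darwin_core_template()
        assert all(not f.mandatory and f.parser == "free-text" for f in spec.fields)

    def test_field_names_unique(self):
        spec = default_darwin_core_template()
        names = [f.name for f in spec.fields]
        assert len(set(names)) == len(names)

    def test_reserved_name_resolves(self):
        assert get_template("dwc-simple").name == "dwc-simple"
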