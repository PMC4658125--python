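import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from drawerseg.imaging_io import Box, Document, SourceImage

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

_DENOM = 10**6  # normalized coords live on a 6-decimal grid


@st.composite
def norm_rects(draw):
    """Valid normalized rectangles, exactly representable at 6 decimals."""
    x0 = draw(st.integers(0, _DENOM - 1))
    x1 = draw(st.integers(x0 + 1, _DENOM))
    y0 = draw(st.integers(0, _DENOM - 1))
    y1 = draw(st.integers(y0 + 1, _DENOM))
    return (x0 / _DENOM, y0 / _DENOM, x1 / _DENOM, y1 / _DENOM)


@st.composite
def boxes(draw):
    rect = draw(norm_rects())
    rotation = draw(st.sampled_from([0, 90, 180, 270]))
    fields = draw(
        st.dictionaries(
            st.text("abcdefgh", min_size=1, max_size=6),
            st.text("xyz 0123", max_size=8),
            max_size=3,
        )
    )
    return Box(rect=rect, rotation=rotation, fields=fields)


@st.composite
def documents(draw):
    return Document(
        scan_path=draw(st.sampled_from(["scan_a.tif", "d/scan_b.png"])),
        thumbnail_path=draw(st.one_of(st.none(), st.just("scan_a_thumbnail.jpg"))),
        thumbnail_width=draw(st.integers(1, 8192)),
        boxes=draw(st.lists(boxes(), max_size=5)),
        template_name=draw(st.one_of(st.none(), st.just("dwc-simple"))),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def gradient_image(rng):
    """A reproducible 60×80 RGB test image with plenty of structure."""
    pixels = rng.integers(0, 256, size=(60, 80, 3), dtype=np.uint8)
    return SourceImage(pixels=pixels)
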