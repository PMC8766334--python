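import io

import pytest
from PIL import Image

from figweaver.fixtures import FixtureSpec, gen_conflicting_svgs, gen_reference_svg


@pytest.fixture
def reference_doc():
    """One pathway-like fixture with stylesheet, gradient, link and white bg."""
    return gen_reference_svg(seed=1)


@pytest.fixture
def conflicting_pair():
    """Two assets binding the same selectors to different paints."""
    return gen_conflicting_svgs(FixtureSpec(seed=7, n_assets=2))


def make_png(width=64, height=32, color=(10, 200, 30)):
    buf = io.BytesIO()
    Image.new("RGB", (width, height), color).save(buf, format="PNG")
    return buf.getvalue()


def make_gif(width=8, height=8):
    buf = io.BytesIO()
    Image.new("P", (width, height)).save(buf, format="GIF")
    return buf.getvalue()


def make_jpeg(width=8, height=8):
    buf = io.BytesIO()
    Image.new("RGB", (width, height)).save(buf, format="JPEG")
    return buf.getvalue()
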