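import numpy as np
import pytest
from hypothesis import settings

from mycocolor import make_fixture_table, make_swatch_image, SwatchSpec

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table():
    """The bundled 16-entry synthetic reference table."""
    return make_fixture_table()


@pytest.fixture
def swatch(tmp_path):
    """Factory writing a flat-color chroma-key swatch PNG."""

    def _make(fg_color, name="swatch.png", **kw):
        spec = SwatchSpec(fg_color=fg_color, **kw)
        return make_swatch_image(spec, tmp_path / name)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
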