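import numpy as np
import pytest

from loomlab.stimulus import FacetGrid, LoomParams, render_stimulus, sample_facets


@pytest.fixture(scope="session")
def small_loom_params():
    """A small, fast loom for encoder tests (reduced screen and rate)."""
    return LoomParams(l_over_v=80.0, polarity="black", extent_deg=40.0,
                      pixel_pitch_deg=1.0, refresh_rate=120.0,
                      t_start=-1.5, t_end=0.0)


@pytest.fixture(scope="session")
def small_loom_movie(small_loom_params):
    return render_stimulus(small_loom_params)


@pytest.fixture(scope="session")
def small_facet_lum(small_loom_movie):
    grid = FacetGrid.regular(extent_deg=40.0, spacing_deg=2.0)
    return sample_facets(small_loom_movie, grid)
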