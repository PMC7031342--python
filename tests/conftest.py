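import numpy as np
import pytest

from cardioquant.synthetic import CellMovieSpec, make_cell_movie


@pytest.fixture(scope="session")
def small_movie_spec():
    """A quick-to-render contracting-cell movie used across tests."""
    return CellMovieSpec(
        image_size=(256, 256),
        duration=8.0,
        rest_long_axis=160.0,
        rest_short_axis=64.0,
        contraction_ratio=0.876,
        event_onsets=(1.0, 3.5, 6.0),
        noise_sd=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_movie(small_movie_spec):
    return make_cell_movie(small_movie_spec)


@pytest.fixture(scope="session")
def rest_frame(small_movie):
    stack, _ = small_movie
    return stack.frames[0]
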