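import numpy as np
import pytest

from kd2.basis import prep_step
from kd2.synthetic_fixtures import DatasetSpec, make_icons


@pytest.fixture(scope="session")
def const150():
    return prep_step(150)


@pytest.fixture(scope="session")
def const40():
    return prep_step(40)


@pytest.fixture(scope="session")
def icons():
    """The nine benchmark icons for seed 1."""
    return make_icons(9, 60, seed=1)


@pytest.fixture(scope="session")
def small_spec():
    """A reduced benchmark spec that runs in a couple of seconds."""
    return DatasetSpec(
        n_icons=3,
        angles=(0, 180),
        scales=(1.0,),
        canvas=200,
        slots=9,
        n_canvases=1,
        icon_size=40,
        frame=100,
        seed=1,
    )


def centered_frame(pattern: np.ndarray, frame: int, fill: float = 0.0) -> np.ndarray:
    """Place a pattern at the centre of a frame-by-frame image."""
    f = np.full((frame, frame), fill)
    h, w = pattern.shape
    top, left = (frame - h) // 2, (frame - w) // 2
    f[top : top + h, left : left + w] = pattern
    return f
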