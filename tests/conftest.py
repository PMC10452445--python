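import numpy as np
import pytest
from hypothesis import settings

from octvessel.phantom import PhantomSpec, generate_phantom
from octvessel.stack_io import StackGeometry

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


SMALL_GEOMETRY = StackGeometry(width_px=64, height_px=64, n_frames=12)


def small_phantom_spec(**overrides) -> PhantomSpec:
    """A miniature acquisition: 64×64 frames, 12 frames deep, ring at 28 px,
    2-frame central depression, three tubes of 20–30 µm radius."""
    defaults = dict(
        geometry=SMALL_GEOMETRY,
        n_open=2,
        n_closed=1,
        radius_um_range=(20.0, 30.0),
        tortuosity=0.0,
        max_extent_um=120.0,
        speckle_sigma=0.0,
        depth_decay_um=150.0,
        blur_sigma0_px=0.5,
        blur_gain_per_frame=0.02,
        ring_radius_px=28,
        depression_frames=2,
        depression_radius_px=8,
        seed=7,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def small_phantom():
    """Noise-free miniature phantom shared by cross-module tests."""
    return generate_phantom(small_phantom_spec())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
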