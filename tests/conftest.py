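import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pyrotex import morphometry as morph
from pyrotex import synthetic as syn

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_cambium_series():
    """Rendered image series for the cambium preset without trajectory noise,
    plus the generating table (used as ground truth)."""
    preset = dataclasses.replace(syn.PRESETS["cambium"], noise_sd=0.0)
    traj = syn.generate_area_trajectory(preset, seed=11)
    series = syn.render_image_series(traj, shape_seed=11, frame_shape=(192, 192))
    return series, traj


@pytest.fixture(scope="session")
def default_surface():
    """One default synthetic rough surface with its rendered tilt pair and
    true disparity field."""
    hmap, truth = syn.generate_height_map(
        syn.SurfaceSpec(grid_shape=(256, 256)), seed=5
    )
    pair, disparity = syn.render_tilt_pair(hmap, tilt_angle=15.0, seed=5)
    return hmap, truth, pair, disparity


@pytest.fixture()
def square_frame():
    """Bright 64x64 frame holding one 10x10 dark square (area 100 px)."""
    img = np.full((64, 64), 200, dtype=float)
    img[20:30, 25:35] = 40
    return img


def make_series(frames):
    n = len(frames)
    return morph.ThermalImageSeries(
        frames=[np.asarray(f, dtype=float) for f in frames],
        time_s=np.arange(n, dtype=float) * 30.0,
        temperature_C=22.0 + 2.5 * np.arange(n, dtype=float),
    )
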