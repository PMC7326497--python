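import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

logging.getLogger("guvkin").setLevel(logging.ERROR)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def noiseless_scene():
    """A small noiseless, blur-free scene: the forward-model oracle case."""
    from guvkin import KineticParams, SimulationScene, place_guvs

    guvs = place_guvs(
        6, np.random.default_rng(5), image_shape=(192, 192),
        radius_range_um=(6.0, 8.0), min_separation_um=2.0,
    )
    return SimulationScene(
        image_shape=(192, 192),
        guvs=guvs,
        psf_sigma_um=0.0,
        kinetics=KineticParams(rate_au_per_min=1.0),
        seed=3,
    )


@pytest.fixture(scope="session")
def noiseless_movie(noiseless_scene):
    from guvkin import simulate_timelapse

    return simulate_timelapse(noiseless_scene, noiseless=True)


@pytest.fixture(scope="session")
def noisy_movie():
    """One default-noise fixture condition with its ground truth."""
    from guvkin import fixture, simulate_timelapse

    scene = fixture("FIG1C", seed=2)["CI"]
    return simulate_timelapse(scene)


def regions_from_truth(gt, n_frames, pixel_size_um=0.25):
    """Build GUVRegion objects straight from simulator ground truth."""
    from guvkin.segment import GUVRegion

    regions = []
    for i, mask in enumerate(gt.masks):
        rows, cols = np.nonzero(mask)
        reg = GUVRegion(
            label=i + 1,
            centroid=gt.centers_px[i],
            radius_px=gt.radii_um[i] / pixel_size_um,
            radius_um=gt.radii_um[i],
            circularity=1.0,
        )
        for t in range(n_frames):
            reg.membrane_pixels[t] = (rows, cols)
        regions.append(reg)
    return regions
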