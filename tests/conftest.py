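import warnings

import numpy as np
import pytest

from pupastat import imaging
from pupastat.synth import SimImageConfig, plan_film, rasterize_film

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def film_pair():
    """One planned film rasterized twice: normal orientation and after a
    180-degree rotation of coordinates, with independent noise."""
    cfg = SimImageConfig(n_pupae=60, touch_prob=0.5)
    layout = plan_film(cfg, seed=11)
    img1 = rasterize_film(layout, rotated=False, noise_seed=22)
    img2 = rasterize_film(layout, rotated=True, noise_seed=23)
    return cfg, layout, img1, img2


@pytest.fixture(scope="session")
def measured_film(film_pair):
    cfg, layout, img1, _ = film_pair
    records = imaging.measure_film(img1, film_id="fixture")
    return cfg, layout.truth_table(), img1, records


def capsule_image(theta_deg=0.0, length_px=100.0, width_px=29.0, size=220,
                  center=None, background=230.0, intensity=40.0):
    """Noise-free anti-aliased capsule for oracle tests."""
    import math

    from pupastat.synth.film import _paint_capsule, _segment_endpoints

    canvas = np.full((size, size), background)
    if center is None:
        center = (size / 2.0, size / 2.0)
    p0, p1 = _segment_endpoints(center[0], center[1],
                                math.radians(theta_deg), length_px, width_px)
    _paint_capsule(canvas, p0, p1, width_px / 2.0, intensity, background)
    return canvas
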