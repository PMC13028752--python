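import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rbcdeform as r

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noise_free_background():
    """Streamline background spec without sensor noise."""
    return r.BackgroundSpec(noise_sd=0.0)


@pytest.fixture(scope="session")
def um_config():
    """Pipeline config with size criteria in micrometres (physical RBC scale)."""
    return r.PipelineConfig(criteria_units="micrometers")


@pytest.fixture(scope="session")
def synthetic_image(noise_free_background):
    """One deterministic 400x400 image with 20 ground-truthed cells."""
    return r.generate_image(noise_free_background, 20, seed=42)


def match_truth(detection, truth, max_dist=4.0):
    """Ground-truth cell nearest to a detection's centroid, or None."""
    best = min(
        truth.cells,
        key=lambda t: math.hypot(
            detection.centroid_x - t.center_x, detection.centroid_y - t.center_y
        ),
    )
    d = math.hypot(
        detection.centroid_x - best.center_x, detection.centroid_y - best.center_y
    )
    return best if d <= max_dist else None


@pytest.fixture(scope="session")
def rasterize_ellipse():
    """Pixel-centre rasterizer for a rotated ellipse (test oracle)."""

    def _raster(a, b, theta_deg, cx, cy, size=40):
        th = math.radians(theta_deg)
        pts = []
        for y in range(size):
            for x in range(size):
                dx, dy = x - cx, y - cy
                u = dx * math.cos(th) + dy * math.sin(th)
                v = -dx * math.sin(th) + dy * math.cos(th)
                if (u / a) ** 2 + (v / b) ** 2 <= 1:
                    pts.append((y, x))
        return np.array(pts, dtype=int)

    return _raster
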