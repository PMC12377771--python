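import math

import numpy as np
import pytest

from cz3geom.geometry import Polygon2D
from cz3geom.synthetic import generate, stage_preset


def random_star_polygon(rng, n_vertices=12, r_min=0.5, r_max=1.5,
                        center=(0.0, 0.0), scale=1.0):
    """Random simple polygon, star-shaped about its center.

    Angles are built from bounded positive gaps so every angular step
    (including the wrap-around) stays well below pi, which guarantees the
    radial chain never self-intersects.
    """
    gaps = rng.uniform(0.5, 1.5, n_vertices)
    ang = 2.0 * math.pi * np.cumsum(gaps) / gaps.sum()
    ang += rng.uniform(0.0, 2.0 * math.pi)
    rad = rng.uniform(r_min, r_max, n_vertices) * scale
    pts = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
    return Polygon2D(pts + np.asarray(center))


def regular_polygon(n, radius=1.0, center=(0.0, 0.0)):
    t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    return Polygon2D(np.column_stack([radius * np.cos(t),
                                      radius * np.sin(t)])
                     + np.asarray(center))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def preset_ii_spheroid():
    """One mid-sized stage-II synthetic spheroid shared across tests."""
    return generate(stage_preset("II", seed=11, n_cells=300))
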