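import numpy as np
import pytest

from oneshotshapes.contour import ClosedContour, resample_contour
from oneshotshapes.synthetic import generate_cohort


@pytest.fixture()
def square():
    return ClosedContour(np.array([[0.0, 0.0], [1, 0], [1, 1], [0, 1]]))


@pytest.fixture()
def circle1000():
    th = np.linspace(0, 2 * np.pi, 1000, endpoint=False)
    return ClosedContour(np.column_stack([np.cos(th), np.sin(th)]))


def random_simple_polygon(rng: np.random.Generator, n: int = 20
                          ) -> ClosedContour:
    """Star-shaped polygon: simple by construction, arbitrary otherwise."""
    th = np.sort(rng.uniform(0, 2 * np.pi, n))
    r = rng.uniform(0.5, 1.5, n)
    return ClosedContour(np.column_stack([r * np.cos(th), r * np.sin(th)]))


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured cohort shared across tests."""
    return generate_cohort(n_drawers=4, n_variations_per_exemplar_per_drawer=6,
                           seed=5)
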