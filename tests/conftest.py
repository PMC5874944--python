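import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gridtr

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cell_lines():
    return gridtr.load_cell_lines()


@pytest.fixture(scope="session")
def tumor_classes(cell_lines):
    return {
        name: cell_lines[name]
        for name in ("radiosensitive", "semisensitive", "radioresistant")
    }


@pytest.fixture(scope="session")
def normal_tissue():
    return gridtr.NORMAL_TISSUE


@pytest.fixture
def canonical15():
    return gridtr.canonical_profile(15.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)


def random_profile(rng):
    """A random but physically plausible single-hole profile."""
    hole = rng.uniform(0.4, 1.5)
    spacing = rng.uniform(hole + 0.2, hole + 1.2)
    geometry = gridtr.GridGeometry(hole_diameter=hole, spacing=spacing)
    model = gridtr.ProfileModelParams(
        valley_fraction=rng.uniform(0.05, 0.6),
        penumbra_sigma=rng.uniform(0.5, 3.0),
        radial_step=0.1,
    )
    return gridtr.make_single_hole_profile(geometry, rng.uniform(5.0, 25.0), model)
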