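import numpy as np
import pytest

from cuffsim.geometry import NerveConfig, synthesize_nerve
from cuffsim.population import default_composition, place_fibers
from cuffsim.benchmarks import straight_fiber_potentials, make_case


@pytest.fixture(scope="session")
def small_nerve():
    """Three-fascicle straight-ish nerve used across placement tests."""
    return synthesize_nerve(
        NerveConfig(n_fascicles=3, length=20.0, epineurium_radius=1.0,
                    curvature_amplitude=0.05),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_population(small_nerve):
    comp = default_composition(120)
    return place_fibers(small_nerve, comp, clustering_strength=0.5, seed=7)


@pytest.fixture()
def straight_potentials():
    """(z, potentials) for a 20 mm straight fiber, source at 1 mm."""
    return straight_fiber_potentials(20.0, 1.0)


@pytest.fixture()
def fiber_case():
    """Factory for single-fiber threshold cases."""
    return make_case
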