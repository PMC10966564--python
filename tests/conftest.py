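import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from evanstim import (
    FiberBeam,
    StimulationProtocol,
    chip_geometry,
    facet_geometry,
    solve_modes,
)
from evanstim.synthetic import NoiseModel, demo_layout, generate_calcium_movie


@pytest.fixture(scope="session")
def chip_modes():
    """First three TE-like modes of the water-clad stimulation waveguide.

    Session-scoped: the eigensolve is the most expensive fixture in the suite
    and every consumer treats the solutions as read-only.
    """
    return solve_modes(chip_geometry(), n_modes=3)


@pytest.fixture(scope="session")
def facet_mode():
    """Fundamental mode of the dry (air-clad) edge-coupling chip."""
    return solve_modes(facet_geometry(), n_modes=1)[0]


@pytest.fixture(scope="session")
def fiber_beam():
    return FiberBeam()


@pytest.fixture(scope="session")
def default_protocol():
    return StimulationProtocol()


@pytest.fixture(scope="session")
def waveguide_movie(default_protocol):
    """One waveguide-stimulation movie plus its ground truth (seed 0)."""
    layout = demo_layout(seed=0)
    return generate_calcium_movie(
        layout, default_protocol, stimulation_mode="waveguide", noise=NoiseModel(seed=0)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
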