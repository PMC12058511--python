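import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_domain():
    from lecmech import CylinderDomain

    return CylinderDomain(diameter=45.0, axial_length=50.0)


@pytest.fixture(scope="session")
def default_domain():
    from lecmech import CylinderDomain

    return CylinderDomain()


@pytest.fixture(scope="session")
def puzzle_default(default_domain):
    from lecmech import PuzzleParams, generate_puzzle_tessellation

    return generate_puzzle_tessellation(default_domain, PuzzleParams(rng_seed=0))


@pytest.fixture(scope="session")
def puzzle_small(small_domain):
    """Reduced tessellation used for FEM-speed-sensitive tests."""
    from lecmech import PuzzleParams, generate_puzzle_tessellation

    return generate_puzzle_tessellation(
        small_domain, PuzzleParams(n_cells=6, rng_seed=1)
    )


@pytest.fixture(scope="session")
def mesh_small(puzzle_small):
    from lecmech import extrude_and_mesh

    return extrude_and_mesh(puzzle_small, depth=2.0, max_triangle_area=10.0)


def scenario_config(seed: int, **kw):
    """Reduced-size scenario configuration shared by FEM comparison tests."""
    from lecmech import CylinderDomain, PuzzleParams, ScenarioConfig

    defaults = dict(
        domain=CylinderDomain(45.0, 50.0),
        puzzle=PuzzleParams(n_cells=6, rng_seed=seed),
        max_triangle_area=10.0,
        n_stations=25,
        end_margin=8.0,
    )
    defaults.update(kw)
    return ScenarioConfig(**defaults)


@pytest.fixture(scope="session")
def rosette():
    th = np.linspace(0, 2 * np.pi, 512, endpoint=False)
    r = 10.0 * (1 + 0.3 * np.sin(5 * th))
    return np.column_stack([r * np.cos(th), r * np.sin(th)])
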