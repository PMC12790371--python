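import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rod_phantom():
    from saxstt.phantom import make_phantom

    return make_phantom({"recipe": "single_rod", "shape": (16, 16, 16)})


@pytest.fixture(scope="session")
def rod_geometry(rod_phantom):
    from saxstt.geometry import geometry_for_phantom, tomo_rotations

    return geometry_for_phantom(
        rod_phantom, tomo_rotations(12, [0.0, 22.5, 45.0]), q_edges=[0.5, 0.6]
    )


@pytest.fixture(scope="session")
def rod_scans(rod_phantom, rod_geometry):
    from saxstt.simulate import simulate_tomogram

    return simulate_tomogram(rod_phantom, rod_geometry, noiseless=True)


@pytest.fixture(scope="session")
def sphere_quad():
    from saxstt.harmonics import sphere_quadrature

    return sphere_quadrature(50, 200)
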