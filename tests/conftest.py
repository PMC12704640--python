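import numpy as np
import pytest

from desimri.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One mid-severity phantom at 1 mm, shared across read-only tests."""
    spec = PhantomSpec(desh_severity=0.5, seed=11)
    vol, truth = generate_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def small_spec():
    """A reduced-size phantom spec for fast geometry tests."""
    return PhantomSpec(
        brain_semi_axes=(52.0, 64.0, 48.0),
        sylvian_center_x_mm=32.2,
        sylvian_width_mm=6.0,
        sylvian_height_mm=16.0,
        slit_r0_mm=30.0,
        slit_r1_mm=44.0,
        desh_severity=0.5,
        noise_sd=3.0,
        seed=7,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
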