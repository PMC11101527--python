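import numpy as np
import pytest

from dermafiber.synthetic_data import (CurveSpec, FiberPhantomSpec,
                                       gen_fiber_stack, gen_stress_strain)
from dermafiber.vonmises import VonMisesMixture


@pytest.fixture(scope="session")
def parallel_tube_phantom():
    """Sparse phantom of straight tubes along the stretch axis (θ≈0, φ≈90)."""
    spec = FiberPhantomSpec(
        shape=(24, 96, 96),
        theta_mixture=VonMisesMixture(b=0, w=1.0, alpha1=0.001, a1=80.0,
                                      alpha2=90.0, a2=80.0),
        phi_concentration=200.0, target_fill=0.08, noise_sd=0.0, seed=2)
    return gen_fiber_stack(spec)


@pytest.fixture(scope="session")
def two_family_phantom():
    """Phantom with the 45°/135° two-family structure typical of dermis."""
    spec = FiberPhantomSpec(
        shape=(24, 96, 96),
        theta_mixture=VonMisesMixture(b=0, w=0.5, alpha1=45.0, a1=8.0,
                                      alpha2=135.0, a2=8.0),
        phi_concentration=100.0, target_fill=0.25, noise_sd=3.0, seed=11)
    return gen_fiber_stack(spec)


@pytest.fixture(scope="session")
def default_curve():
    return gen_stress_strain(CurveSpec(noise_sd=0.0, seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
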