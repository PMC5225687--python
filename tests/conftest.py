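import numpy as np
import pytest

from thermofac.phantom import PhantomSpec, make_phantom
from thermofac.thermio import Contour


def circle_contour(center, radius, n=100):
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return Contour(points=np.stack([center[0] + radius * np.cos(theta),
                                    center[1] + radius * np.sin(theta)],
                                   axis=1))


@pytest.fixture(scope="session")
def noiseless_phantom():
    """One shared 128x128 noiseless layered phantom (r_core 12, 3 layers)."""
    return make_phantom(PhantomSpec(noise_sd=0.0, r_core=12.0, n_layers=3,
                                    layer_width=6.0, seed=1))


@pytest.fixture(scope="session")
def noisy_phantom():
    return make_phantom(PhantomSpec(noise_sd=0.2, r_core=12.0, n_layers=3,
                                    layer_width=6.0, seed=3))
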