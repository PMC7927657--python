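import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sinkscale as sk

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def seawater():
    return sk.default_seawater()


@pytest.fixture
def oil():
    return sk.default_mineral_oil()


@pytest.fixture
def resin():
    return sk.default_resin()


@pytest.fixture
def test_material():
    return sk.default_test_material()


@pytest.fixture
def foram_sphere():
    """A 900 um sphere standing in for a foraminifera-sized particle."""
    return sk.ParticleGeometry.sphere(900e-6)


def bisect_terminal_re(geom, material, fluid, drag, g=sk.G_STANDARD,
                       lo=1e-6, hi=1e5, iters=200):
    """Independent bisection oracle for the terminal Reynolds number.

    Deliberately avoids the package's root-finding path: plain interval
    bisection on the sign of C_D^F(Re) - C_D(Re).
    """

    def f(Re):
        cdf = (2.0 * g * geom.V * (material.density - fluid.density)
               * geom.L**2 * fluid.density
               / (geom.A * fluid.viscosity**2 * Re**2))
        return cdf - drag(Re)

    a, b = lo, hi
    fa = f(a)
    for _ in range(iters):
        m = np.sqrt(a * b)  # bisect in log space
        fm = f(m)
        if np.sign(fm) == np.sign(fa):
            a, fa = m, fm
        else:
            b = m
    return np.sqrt(a * b)
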