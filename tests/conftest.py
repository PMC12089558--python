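import numpy as np
import pytest

from stenokit.phantoms import Anomaly, PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def tube50():
    """Noiseless single tube, radius 6 px, one 50% stenosis mid-vessel."""
    spec = PhantomSpec(
        topology="single",
        base_radius=6.0,
        angle=20.0,
        anomalies=[Anomaly("tube", 0.5, "stenosis", 0.5, 25.0)],
        noise=0.0,
        seed=1,
    )
    img, truth = make_phantom(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def healthy_tube():
    spec = PhantomSpec(topology="single", base_radius=8.0, angle=35.0, noise=0.0, seed=2)
    img, truth = make_phantom(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def noisy_tube60():
    """Rendered (noise 0.03) tube with a 60% stenosis, for full-pipeline tests."""
    spec = PhantomSpec(
        topology="single",
        base_radius=8.0,
        angle=35.0,
        anomalies=[Anomaly("tube", 0.5, "stenosis", 0.6, 25.0)],
        noise=0.03,
        seed=3,
    )
    img, truth = make_phantom(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def iliac_tree():
    """Aorto-iliac tree with an 80% stenosis on the left common iliac."""
    spec = PhantomSpec(
        topology="aorto_iliac",
        base_radius=9.0,
        anomalies=[Anomaly("CIA_left", 0.5, "stenosis", 0.8, 22.0)],
        noise=0.0,
        seed=4,
    )
    img, truth = make_phantom(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def healthy_tree():
    spec = PhantomSpec(topology="aorto_iliac", base_radius=8.0, noise=0.03, seed=5)
    img, truth = make_phantom(spec)
    return spec, img, truth


def straight_tube(shape=(40, 200), radius=5, row=None):
    """Axis-aligned analytic tube mask: |y - row| <= radius."""
    mask = np.zeros(shape, dtype=bool)
    r0 = shape[0] // 2 if row is None else row
    mask[r0 - radius : r0 + radius + 1, :] = True
    return mask
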