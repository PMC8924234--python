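import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def session_rng():
    return np.random.default_rng(98765)


def disc_field(canvas: int, diameter: float, value: float = 1.0,
               center: tuple[float, float] | None = None) -> np.ndarray:
    """Analytic disc indicator field (pixel-center membership)."""
    if center is None:
        center = (canvas / 2.0, canvas / 2.0)
    yy, xx = np.mgrid[0:canvas, 0:canvas]
    r = diameter / 2.0
    return value * (((xx - center[0]) ** 2 + (yy - center[1]) ** 2) <= r * r)
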