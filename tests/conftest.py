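import numpy as np
import pytest

from earblink.geometry import EyePoints


def eye_from_distances(a: float, b: float, c: float) -> EyePoints:
    """Construct an eye whose lid distances are exactly (a, b) and width c."""
    return EyePoints(
        p1=(0.0, 0.0),
        p2=(c / 4.0, a / 2.0),
        p3=(3.0 * c / 4.0, b / 2.0),
        p4=(c, 0.0),
        p5=(3.0 * c / 4.0, -b / 2.0),
        p6=(c / 4.0, -a / 2.0),
    )


def random_eye(rng: np.random.Generator) -> EyePoints:
    pts = rng.uniform(-100.0, 100.0, size=(6, 2))
    # keep the corner distance well away from zero
    pts[3] = pts[0] + rng.uniform(1.0, 50.0) * _unit(rng)
    return EyePoints(*map(tuple, pts))


def _unit(rng: np.random.Generator) -> np.ndarray:
    theta = rng.uniform(0, 2 * np.pi)
    return np.array([np.cos(theta), np.sin(theta)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
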