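import numpy as np
import pytest

from vorogis.points import PointPattern, Rect


@pytest.fixture
def unit_square_corners():
    return PointPattern(
        np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]),
        frame=Rect(0, 0, 1, 1),
    )


def grid_pattern(k: int) -> PointPattern:
    """k×k unit-spaced lattice pattern."""
    xs, ys = np.meshgrid(np.arange(k, dtype=float), np.arange(k, dtype=float))
    return PointPattern(
        np.column_stack([xs.ravel(), ys.ravel()]), frame=Rect(0, 0, k - 1.0, k - 1.0)
    )


def random_pattern(n: int, seed: int, size: float = 100.0) -> PointPattern:
    rng = np.random.default_rng(seed)
    return PointPattern(rng.uniform(0, size, (n, 2)), frame=Rect(0, 0, size, size))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
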