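import numpy as np
import pytest

from phyllo import Contour, PHParams


@pytest.fixture
def unit_square() -> Contour:
    return Contour(
        points=np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]),
        id="square",
    )


@pytest.fixture
def circle_factory():
    def make(radius=1.0, center=(0.0, 0.0), n=360, id="circle") -> Contour:
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        pts = np.column_stack(
            [center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)]
        )
        return Contour(points=pts, id=id)

    return make


@pytest.fixture
def small_params() -> PHParams:
    """Reduced descriptor settings for fast unit tests."""
    return PHParams(h=0.03, resolution=128, n_resample=400, n_annuli=8, n_levels=60)


def rotate(points: np.ndarray, degrees: float) -> np.ndarray:
    a = np.deg2rad(degrees)
    R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    return points @ R.T
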