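import math

import numpy as np
import pytest

from sahquant.geometry import Contour, Polyline


def circle_contour(radius: float = 1.0, n: int = 720, center=(0.0, 0.0)) -> Contour:
    theta = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return Contour(
        np.stack(
            [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)], axis=1
        )
    )


def ellipse_contour(a: float, b: float, n: int = 720) -> Contour:
    theta = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return Contour(np.stack([a * np.cos(theta), b * np.sin(theta)], axis=1))


def rectangle_contour(w: float, h: float) -> Contour:
    return Contour(np.array([[0.0, 0.0], [w, 0.0], [w, h], [0.0, h]]))


@pytest.fixture
def unit_square() -> Contour:
    return rectangle_contour(1.0, 1.0)


@pytest.fixture
def sham_profile():
    """One deterministic SHAM phantom with its ground truth."""
    from sahquant.synthetic import PhantomConfig, make_capillary_phantom

    return make_capillary_phantom(PhantomConfig(group_label="SHAM", seed=42), 0, 0)


__all__ = ["circle_contour", "ellipse_contour", "rectangle_contour", "Polyline"]
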