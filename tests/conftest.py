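import math

import numpy as np
import pytest

from surveylearn.geometry import Anchor, Bearing, Point2D, RouteMap, TrainingPath
from surveylearn.bidimreg import PointConfig


@pytest.fixture
def l_route() -> RouteMap:
    """Hand-built L-shaped route with known geometry.

    Start (0,0) -> north 100 m -> turn -> east 100 m -> goal. One landmark on
    each leg, facing along the walked segment.
    """
    v = [Point2D(0, 0), Point2D(0, 100), Point2D(100, 100)]
    anchors = {
        "start": Anchor("start", v[0]),
        "landmark1": Anchor("landmark1", Point2D(0, 50), Bearing(0)),
        "turn1": Anchor("turn1", v[1]),
        "landmark2": Anchor("landmark2", Point2D(50, 100), Bearing(90)),
        "goal": Anchor("goal", v[2]),
    }
    return RouteMap(name="L", vertices=v, anchors=anchors)


@pytest.fixture
def square_config() -> PointConfig:
    return PointConfig.from_array(
        ["a", "b", "c", "d"], np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    )


def similarity_transform(xy: np.ndarray, scale: float, rotation_deg: float,
                         tx: float, ty: float, reflect: bool = False) -> np.ndarray:
    """Apply a planar similarity (optionally with reflection) to (n,2) points."""
    pts = np.asarray(xy, dtype=float)
    if reflect:
        pts = pts * np.array([1.0, -1.0])
    th = math.radians(rotation_deg)
    R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    return scale * pts @ R.T + np.array([tx, ty])


@pytest.fixture
def triangle_path() -> TrainingPath:
    """Triangle training path: S=(0,0), corner (4,0), E=(2,3); north at 0 deg."""
    return TrainingPath(
        shape="triangle",
        vertices=[Point2D(0, 0), Point2D(4, 0), Point2D(2, 3)],
        north_bearing=0.0,
    )
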