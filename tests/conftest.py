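import numpy as np
import pandas as pd
import pytest

from icmsort.tracks import TrackSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_tracks(positions: dict, fates: dict, frame_interval: float = 20.0,
                reporter: dict | None = None) -> TrackSet:
    """Build a TrackSet from {cell_id: (n_frames, 3) array} and {cell_id: fate}."""
    rows = []
    for cid, pos in positions.items():
        pos = np.asarray(pos, float)
        for k, p in enumerate(pos):
            rows.append({
                "track_id": cid, "parent_id": -1,
                "t_min": k * frame_interval,
                "x_um": p[0], "y_um": p[1], "z_um": p[2],
                "fate": fates[cid],
                "reporter": (reporter[cid][k] if reporter else 0.0),
            })
    return TrackSet(pd.DataFrame(rows), frame_interval=frame_interval)


@pytest.fixture
def two_cell_tracks():
    """Two static cells at (±5, 0, 0): centroid at origin, both r = 5."""
    pos = {0: [[5.0, 0, 0]] * 4, 1: [[-5.0, 0, 0]] * 4}
    return make_tracks(pos, {0: "PRE", 1: "EPI"})


@pytest.fixture
def circle_contour():
    """Digitised circle of radius 50 px, CCW, pixel size 1 μm/px."""
    from icmsort.quantify import Contour2D

    theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    pts = 50.0 * np.column_stack([np.cos(theta), np.sin(theta)])
    return Contour2D(pts, pixel_size=1.0, closed=True,
                     cavity_axis=np.array([1.0, 0.0]))
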