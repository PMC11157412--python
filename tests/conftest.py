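import numpy as np
import pytest

from locokinetics import CalibrationSet, PoseTrack, calibrate


def make_track(coords: dict, fps: float = 30.0, units: str = "cm",
               likelihood: dict | None = None, arena: str | None = None,
               y_down: bool = True) -> PoseTrack:
    """Build a PoseTrack from landmark -> (n, 2) coordinate arrays."""
    landmarks = list(coords)
    arrs = [np.asarray(coords[bp], dtype=float) for bp in landmarks]
    n = len(arrs[0])
    xy = np.stack(arrs, axis=1)
    lik = np.full((n, len(landmarks)), 0.95)
    for bp, vals in (likelihood or {}).items():
        lik[:, landmarks.index(bp)] = vals
    return PoseTrack(landmarks=landmarks, xy=xy, likelihood=lik, fps=fps,
                     units=units, arena=arena, y_down=y_down)


CORRIDOR_MARKERS = [f"cal_marker_{i}" for i in (1, 2, 3, 4)]
CORNERS = [f"corner_{i}" for i in (1, 2, 3, 4)]


@pytest.fixture
def corridor_cal():
    return CalibrationSet(markers=CORRIDOR_MARKERS, spacing_cm=5.0)


@pytest.fixture
def arena_cal():
    return CalibrationSet(markers=CORNERS, spacing_cm=40.0)


def calibrated(track, cal):
    return calibrate(track, cal)
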