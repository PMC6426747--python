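"""Grasp-event detection and pro/supination angle extraction.

Marker conventions: lab frame with x to the right, y to the front
(perpendicular to the drawer faces) and z up; markers on the acromion (AC),
radial (RS) and ulnar (US) styloid and third metacarpal (MC), positions in
millimetres.  The grasp moment of a trial is the first local maximum of the
MC marker's y (depth) trajectory; the pro/supination angle is the
four-quadrant angle of the wrist axis RS - US projected onto the x-z plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .exceptions import InvalidInputError, NoEventError, ParseError

__all__ = [
    "MarkerTrajectory",
    "GraspEvent",
    "detect_grasp_frame",
    "prosupination_angle",
    "grasp_event",
    "read_trajectory",
    "shoulder_height",
]

MARKERS = ("AC", "RS", "US", "MC")


@dataclass(frozen=True)
class MarkerTrajectory:
    """Time-ordered 3-D marker positions.

    ``positions`` maps marker label -> (n_frames, 3) array in mm, all
    markers sharing the same frame count; ``frame_rate`` in Hz.
    """

    positions: dict
    frame_rate: float = 200.0

    def __post_init__(self) -> None:
        lengths = {k: np.asarray(v).shape for k, v in self.positions.items()}
        n = None
        for k, shape in lengths.items():
            if len(shape) != 2 or shape[1] != 3:
                raise InvalidInputError(f"marker {k}: expected (n_frames, 3), got {shape}")
            if n is None:
                n = shape[0]
            elif shape[0] != n:
                raise InvalidInputError("markers have differing frame counts")
        if n is None or n < 3:
            raise InvalidInputError("need >= 3 frames")
        for k, v in self.positions.items():
            if not np.all(np.isfinite(v)):
                raise InvalidInputError(f"marker {k} has non-finite positions")

    @property
    def n_frames(self) -> int:
        return next(iter(self.positions.values())).shape[0]

    def marker(self, label: str) -> np.ndarray:
        return np.asarray(self.positions[label], dtype=float)


@dataclass(frozen=True)
class GraspEvent:
    """Detected grasp moment: interior frame index and angle in degrees."""

    frame_index: int
    angle: float


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with truncated windows at the edges."""
    kernel = np.ones(window)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y), kernel, mode="same")
    return num / den


def detect_grasp_frame(
    y_trajectory, smooth_window: int = 5, prominence_frac: float = 0.1
) -> int:
    """Index of the first local maximum of a depth trajectory.

    The trace is smoothed with a centered moving average (``smooth_window``
    frames; skipped for traces shorter than twice the window, where
    smoothing would wash out the structure) and candidate peaks must clear a
    prominence of ``prominence_frac`` times the raw trace's total excursion.
    For a plateau maximum the first frame of the plateau is returned.
    """

    y = np.asarray(y_trajectory, dtype=float).ravel()
    if y.size < 3:
        raise InvalidInputError("need >= 3 frames for event detection")
    if not np.all(np.isfinite(y)):
        raise InvalidInputError("trajectory has non-finite values")
    excursion = float(np.ptp(y))
    if excursion == 0.0:
        raise NoEventError("flat trajectory has no local maximum")
    ys = y if y.size < 2 * smooth_window else _moving_average(y, smooth_window)
    peaks, props = find_peaks(
        ys, prominence=prominence_frac * excursion, plateau_size=(1, None)
    )
    if peaks.size == 0:
        raise NoEventError("no local maximum of sufficient prominence found")
    return int(props["left_edges"][0])


def prosupination_angle(rs, us) -> float:
    """Projected pro/supination angle alpha of the wrist axis, in degrees.

    The wrist vector v = RS - US is projected onto the x-z plane (the plane
    of the drawer faces); alpha is the four-quadrant angle of (v_x, v_z)
    measured from the +z axis toward +x and wrapped to (-180, 180].  alpha
    is 0 when v points straight up (back of the hand to the right);
    pronation tilts v toward +x and increases alpha.
    """

    rs = np.asarray(rs, dtype=float)
    us = np.asarray(us, dtype=float)
    if rs.shape != (3,) or us.shape != (3,):
        raise InvalidInputError("rs and us must be 3-D points")
    v = rs - us
    vx, vz = v[0], v[2]
    if vx == 0.0 and vz == 0.0:
        raise InvalidInputError(
            "wrist axis has zero length in the x-z projection; angle undefined"
        )
    alpha = float(np.degrees(np.arctan2(vx, vz)))
    if alpha <= -180.0:
        alpha += 360.0
    return alpha


def grasp_event(traj: MarkerTrajectory, **detect_kwargs) -> GraspEvent:
    """Detect the grasp frame from MC depth and compute alpha at that frame."""
    frame = detect_grasp_frame(traj.marker("MC")[:, 1], **detect_kwargs)
    angle = prosupination_angle(traj.marker("RS")[frame], traj.marker("US")[frame])
    return GraspEvent(frame_index=frame, angle=angle)


def read_trajectory(path, frame_rate: float = 200.0) -> MarkerTrajectory:
    """Read a long-format trajectory file (columns frame, marker, x, y, z; mm)."""
    df = pd.read_csv(path)
    required = {"frame", "marker", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    positions = {}
    for label, grp in df.groupby("marker"):
        grp = grp.sort_values("frame")
        positions[str(label)] = grp[["x", "y", "z"]].to_numpy(dtype=float)
    return MarkerTrajectory(positions=positions, frame_rate=frame_rate)


def shoulder_height(ac_height_mm: float) -> float:
    """Approximate shoulder-joint-center height: 0.97 x acromion height."""
    return 0.97 * float(ac_height_mm)
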