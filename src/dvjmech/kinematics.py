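"""Sagittal joint and pelvis angles and jump height from marker data.

Angles come from marker-defined segment lines (hip-knee, knee-ankle,
ankle-toe, PSIS-ASIS), not functional joint centres, so a static calibration
trial in neutral standing defines every joint's zero.  Conventions: knee and
hip flexion positive, ankle dorsiflexion positive, pelvic anterior tilt
positive (anterior pelvis markers dipping below the posterior ones), all in
degrees.  Angles are invariant under global translation and uniform scaling
of the marker cloud.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import PELVIS_MARKERS, TrialRecording
from .signal import derivative

JOINTS = ("pelvis", "hip", "knee", "ankle")


class KinematicsError(ValueError):
    pass


@dataclass
class JointSeries:
    """Per-joint time series at the kinematic rate.

    ``angle`` in degrees; ``velocity`` in deg/s once computed; inverse
    dynamics later attaches normalized moments (Nm/kg) and powers (W/kg).
    """

    rate: float
    angle: dict = field(default_factory=dict)
    velocity: dict = field(default_factory=dict)
    moment: dict = field(default_factory=dict)
    power: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.angle.values())))


def _segment_angle_from_down(prox: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """CCW angle (rad) of the proximal->distal line from straight down,
    positive when the distal end sits anterior to the proximal end."""
    d = dist - prox
    lengths = np.hypot(d[:, 0], d[:, 1])
    if np.any(lengths < 1e-9):
        frame = int(np.argmax(lengths < 1e-9))
        raise KinematicsError(f"degenerate zero-length segment at frame {frame}")
    return np.arctan2(d[:, 0], -d[:, 1])


def _xy(markers: dict, label: str) -> np.ndarray:
    return markers[label][:, :2]


def ankle_neutral_offset(static_trial: TrialRecording, side: str = "R") -> float:
    """Static calibration constant for the ankle (rad): mean foot-line angle
    minus shank angle in neutral standing.  Subtracting it makes the standing
    ankle angle zero with dorsiflexion positive."""
    m = static_trial.markers
    a_s = _segment_angle_from_down(_xy(m, f"{side}_KNEE"), _xy(m, f"{side}_ANK"))
    d = _xy(m, f"{side}_TOE") - _xy(m, f"{side}_ANK")
    f = np.arctan2(d[:, 1], d[:, 0])
    return float(np.mean(f - a_s))


def joint_angles(markers: dict, rate: float, neutral_ankle_offset: float,
                 side: str = "R") -> JointSeries:
    """Sagittal angle series (deg) from a marker dict of (n, 3) arrays.

    ``neutral_ankle_offset`` comes from :func:`ankle_neutral_offset` on the
    subject's static trial.
    """
    for lab in (f"{side}_HIP", f"{side}_KNEE", f"{side}_ANK", f"{side}_TOE"):
        if lab not in markers:
            raise KinematicsError(f"marker {lab} required for joint angles")
    hip_m = _xy(markers, f"{side}_HIP")
    knee_m = _xy(markers, f"{side}_KNEE")
    ank_m = _xy(markers, f"{side}_ANK")
    toe_m = _xy(markers, f"{side}_TOE")
    ant = 0.5 * (_xy(markers, "RASI") + _xy(markers, "LASI"))
    post = 0.5 * (_xy(markers, "RPSI") + _xy(markers, "LPSI"))

    a_t = _segment_angle_from_down(hip_m, knee_m)
    a_s = _segment_angle_from_down(knee_m, ank_m)
    d_pel = ant - post
    if np.any(np.hypot(d_pel[:, 0], d_pel[:, 1]) < 1e-9):
        raise KinematicsError("degenerate pelvis line")
    tilt = -np.arctan2(d_pel[:, 1], d_pel[:, 0])
    d_foot = toe_m - ank_m
    foot = np.arctan2(d_foot[:, 1], d_foot[:, 0])

    series = JointSeries(rate=rate)
    series.angle = {
        "pelvis": np.rad2deg(tilt),
        "hip": np.rad2deg(a_t + tilt),
        "knee": np.rad2deg(a_t - a_s),
        "ankle": np.rad2deg(foot - a_s - neutral_ankle_offset),
    }
    return series


def angular_velocity(series: JointSeries) -> JointSeries:
    """Attach deg/s velocities (central differences) to a JointSeries."""
    for j, ang in series.angle.items():
        series.velocity[j] = derivative(ang, series.rate, order=1)
    return series


def pelvis_height(markers: dict) -> np.ndarray:
    """Mean height (m) of the four pelvis markers per frame."""
    return np.mean([markers[m][:, 1] for m in PELVIS_MARKERS], axis=0)


def jump_height(dvj_markers: dict, static_markers: dict, rate_kin: float,
                takeoff_time: float) -> float:
    """Jump height in cm: peak pelvis-marker centroid height in the flight
    after take-off minus the mean standing pelvis height."""
    heights = pelvis_height(dvj_markers)
    t = np.arange(heights.size) / rate_kin
    flight = t >= takeoff_time
    if not flight.any():
        raise KinematicsError("no flight frames after the analyzed contact")
    ref = float(np.mean(pelvis_height(static_markers)))
    return float((heights[flight].max() - ref) * 100.0)
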