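"""Phase segmentation and the trial-level outcome variable set.

The contact phase splits at the instant of peak knee flexion into a landing
phase (touchdown to peak knee flexion, eccentric absorption) and a
propulsion phase (peak knee flexion to take-off, concentric generation).
From one analyzed trial the extractor reports the full outcome set: peak
vertical GRF per phase (body-weight multiples), sagittal angles at
touchdown and their landing-phase peaks, landing-phase peak internal
moments (Nm/kg), peak power absorption in landing and generation in
propulsion (W/kg), knee joint stiffness, the three phase durations, and
jump height.

Knee joint stiffness is the ratio of the knee moment change to the knee
angular excursion between touchdown and the instant of peak knee flexion
(values sampled at the two instants, not phase extrema), in Nm/kg/deg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd

from . import signal as sig
from .dynamics import joint_power, newton_euler_planar
from .io import TrialRecording
from .kinematics import (KinematicsError, angular_velocity,
                         ankle_neutral_offset, joint_angles, jump_height)
from .model import build_body_model
from .signal import Events


class MetricsError(ValueError):
    pass


@dataclass
class DVJMetrics:
    """One trial's (or trial-average's) outcome variables.

    Units: GRF peaks in body-weight multiples, angles deg, moments Nm/kg,
    powers W/kg, stiffness Nm/kg/deg, durations ms, jump height cm.
    """

    peak_vgrf_landing: float = np.nan
    peak_vgrf_propulsion: float = np.nan
    pelvic_tilt_ic: float = np.nan
    peak_pelvic_tilt_landing: float = np.nan
    hip_flexion_ic: float = np.nan
    peak_hip_flexion_landing: float = np.nan
    peak_hip_moment_landing: float = np.nan
    peak_hip_power_absorption_landing: float = np.nan
    peak_hip_power_generation_propulsion: float = np.nan
    knee_flexion_ic: float = np.nan
    peak_knee_flexion_landing: float = np.nan
    peak_knee_moment_landing: float = np.nan
    peak_knee_power_absorption_landing: float = np.nan
    peak_knee_power_generation_propulsion: float = np.nan
    ankle_ic: float = np.nan
    peak_ankle_landing: float = np.nan
    peak_ankle_moment_landing: float = np.nan
    peak_ankle_power_absorption_landing: float = np.nan
    peak_ankle_power_generation_propulsion: float = np.nan
    knee_stiffness: float = np.nan
    total_contact_duration: float = np.nan
    landing_duration: float = np.nan
    propulsion_duration: float = np.nan
    jump_height: float = np.nan

    @classmethod
    def field_names(cls):
        return [f.name for f in dc_fields(cls)]

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in self.field_names()}


#: column units for report writers, in field order
METRIC_UNITS = {
    "peak_vgrf_landing": "BW", "peak_vgrf_propulsion": "BW",
    "pelvic_tilt_ic": "deg", "peak_pelvic_tilt_landing": "deg",
    "hip_flexion_ic": "deg", "peak_hip_flexion_landing": "deg",
    "peak_hip_moment_landing": "Nm/kg",
    "peak_hip_power_absorption_landing": "W/kg",
    "peak_hip_power_generation_propulsion": "W/kg",
    "knee_flexion_ic": "deg", "peak_knee_flexion_landing": "deg",
    "peak_knee_moment_landing": "Nm/kg",
    "peak_knee_power_absorption_landing": "W/kg",
    "peak_knee_power_generation_propulsion": "W/kg",
    "ankle_ic": "deg", "peak_ankle_landing": "deg",
    "peak_ankle_moment_landing": "Nm/kg",
    "peak_ankle_power_absorption_landing": "W/kg",
    "peak_ankle_power_generation_propulsion": "W/kg",
    "knee_stiffness": "Nm/kg/deg",
    "total_contact_duration": "ms", "landing_duration": "ms",
    "propulsion_duration": "ms", "jump_height": "cm",
}


def split_phases(idx_ic: int, idx_takeoff: int,
                 knee_angle: np.ndarray) -> tuple[int, tuple, tuple]:
    """Locate peak knee flexion and return the phase windows.

    Returns ``(idx_peak, landing, propulsion)`` with landing the closed
    window [idx_ic, idx_peak] and propulsion the half-open (idx_peak,
    idx_takeoff).  Ties at the peak break to the earliest frame.
    """
    if not 0 <= idx_ic < idx_takeoff <= len(knee_angle):
        raise MetricsError("contact window outside the knee angle series")
    window = knee_angle[idx_ic:idx_takeoff]
    idx_peak = idx_ic + int(np.argmax(window))
    if idx_peak in (idx_ic, idx_takeoff - 1):
        warnings.warn("peak knee flexion at a contact boundary; the landing "
                      "phase is degenerate", stacklevel=2)
    return idx_peak, (idx_ic, idx_peak), (idx_peak, idx_takeoff)


def knee_stiffness(knee_moment: np.ndarray, knee_angle: np.ndarray,
                   idx_ic: int, idx_peak: int,
                   mode: str = "instants") -> float:
    """Knee joint stiffness in Nm/kg/deg over the landing phase.

    ``instants`` (default) uses the moment and angle values sampled at
    touchdown and at peak knee flexion; ``extrema`` divides the phase's
    moment range by the same angular excursion instead.
    """
    rom = knee_angle[idx_peak] - knee_angle[idx_ic]
    if abs(rom) < 1e-9:
        raise MetricsError("zero knee range of motion; stiffness undefined")
    if mode == "instants":
        dm = knee_moment[idx_peak] - knee_moment[idx_ic]
    elif mode == "extrema":
        seg = knee_moment[idx_ic:idx_peak + 1]
        dm = seg.max() - knee_moment[idx_ic]
    else:
        raise MetricsError(f"unknown stiffness mode {mode!r}")
    return float(dm / rom)


@dataclass
class TrialAnalysis:
    """Intermediate products of one analyzed trial."""

    events: Events
    joints: "object"
    kinetics: "object"
    metrics: DVJMetrics


def analyze_trial(trial: TrialRecording, static_trial: TrialRecording,
                  side: str = "R",
                  threshold: float = sig.DEFAULT_THRESHOLD_N,
                  cutoff: float = sig.DEFAULT_CUTOFF_HZ,
                  order: int = sig.DEFAULT_ORDER,
                  anthropometric_table: str = "deLeva1996",
                  stiffness_mode: str = "instants") -> TrialAnalysis:
    """Full single-trial pipeline: events, filtering, kinematics, inverse
    dynamics, and metric extraction for the analyzed (dominant) leg."""
    rate_k = trial.rate_kin
    rate_f = trial.rate_force
    ratio = trial.rate_ratio
    model = build_body_model(trial.subject, anthropometric_table)

    # events on the RAW summed vertical force, then filter everything
    raw_fy = trial.total_vertical_grf()
    intervals = sig.detect_contact_events(raw_fy, rate_f, threshold)
    i0_f, i1_f = sig.select_landing_contact(intervals, rate_f)
    t_ic, t_to = i0_f / rate_f, i1_f / rate_f

    filt_markers = {lab: sig.butterworth_lowpass(arr, rate_k, cutoff, order,
                                                 axis=0)
                    for lab, arr in trial.markers.items()}
    filt_static = {lab: sig.butterworth_lowpass(arr, rate_k, cutoff, order,
                                                axis=0)
                   for lab, arr in static_trial.markers.items()}
    plate_kin = {pid: sig.downsample_force_to_kin(p, rate_f, rate_k,
                                                  cutoff, order, axis=0)
                 for pid, p in trial.plates.items()}
    total_fy_kin = sum(p[:, 1] for p in plate_kin.values())

    static_for_cal = type(static_trial)(
        markers=filt_static, plates=static_trial.plates,
        subject=static_trial.subject, rate_kin=static_trial.rate_kin,
        rate_force=static_trial.rate_force,
        trial_kind=static_trial.trial_kind)
    offset = ankle_neutral_offset(static_for_cal, side=side)
    joints = angular_velocity(joint_angles(filt_markers, rate_k, offset,
                                           side=side))

    idx_ic = int(round(t_ic * rate_k))
    idx_to_excl = int(np.ceil(t_to * rate_k - 1e-9))
    idx_to_excl = min(idx_to_excl, joints.n_frames)
    idx_pk, landing, propulsion = split_phases(
        idx_ic, idx_to_excl, joints.angle["knee"])
    t_pk = idx_pk / rate_k
    events = Events(idx_ic=idx_ic, idx_peak_knee=idx_pk,
                    idx_takeoff=idx_to_excl,
                    idx_ic_force=i0_f, idx_takeoff_force=i1_f)

    kin = newton_euler_planar(filt_markers, plate_kin[side], model, rate_k,
                              side=side, total_grf_bw=total_fy_kin)
    kin = joint_power(kin, joints)
    for j in kin.moment_norm:
        joints.moment[j] = kin.moment_norm[j]
        joints.power[j] = kin.power_norm[j]

    m = DVJMetrics()
    land_sl = slice(landing[0], landing[1] + 1)
    prop_sl = slice(propulsion[0] + 1, propulsion[1])
    grf = kin.grf_bw
    m.peak_vgrf_landing = float(grf[land_sl].max())
    m.peak_vgrf_propulsion = float(grf[prop_sl].max())
    ang = joints.angle
    m.pelvic_tilt_ic = float(ang["pelvis"][idx_ic])
    m.hip_flexion_ic = float(ang["hip"][idx_ic])
    m.knee_flexion_ic = float(ang["knee"][idx_ic])
    m.ankle_ic = float(ang["ankle"][idx_ic])
    m.peak_pelvic_tilt_landing = float(ang["pelvis"][land_sl].max())
    m.peak_hip_flexion_landing = float(ang["hip"][land_sl].max())
    m.peak_knee_flexion_landing = float(ang["knee"][land_sl].max())
    m.peak_ankle_landing = float(ang["ankle"][land_sl].max())
    for joint in ("hip", "knee", "ankle"):
        mom = kin.moment_norm[joint]
        pwr = kin.power_norm[joint]
        setattr(m, f"peak_{joint}_moment_landing", float(mom[land_sl].max()))
        setattr(m, f"peak_{joint}_power_absorption_landing",
                float(pwr[land_sl].min()))
        setattr(m, f"peak_{joint}_power_generation_propulsion",
                float(pwr[prop_sl].max()))
    m.knee_stiffness = knee_stiffness(kin.moment_norm["knee"], ang["knee"],
                                      idx_ic, idx_pk, mode=stiffness_mode)
    m.total_contact_duration = (t_to - t_ic) * 1e3
    m.landing_duration = (t_pk - t_ic) * 1e3
    m.propulsion_duration = (t_to - t_pk) * 1e3
    try:
        m.jump_height = jump_height(filt_markers, filt_static, rate_k, t_to)
    except KinematicsError:
        raise MetricsError("no flight phase after the analyzed contact")
    return TrialAnalysis(events=events, joints=joints, kinetics=kin,
                         metrics=m)


def average_trials(metrics: list[DVJMetrics]) -> DVJMetrics:
    """Field-wise arithmetic mean over repeated trials of one session."""
    if not metrics:
        raise MetricsError("no trials to average")
    out = DVJMetrics()
    for f in DVJMetrics.field_names():
        setattr(out, f, float(np.mean([getattr(x, f) for x in metrics])))
    return out


def metrics_frame(rows: list[dict]) -> pd.DataFrame:
    """Tidy frame (one row per subject x session x trial) from dicts that
    carry identifier keys plus DVJMetrics fields."""
    return pd.DataFrame(rows)
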