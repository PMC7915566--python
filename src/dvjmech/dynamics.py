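"""Planar bottom-up Newton-Euler inverse dynamics for the landing leg.

Each segment (foot, shank, thigh) is treated as a rigid body with inertial
parameters from the anthropometric table.  Starting at the foot, the Newton
equation (sum F = m a_com) and the Euler equation (sum M about the CoM =
I alpha) are solved per frame for the proximal joint reaction force and net
internal joint moment, given the distal loads; the ground reaction force is
applied at the centre of pressure.  Segment CoM accelerations and angular
accelerations come from double-differentiated filtered marker positions.

Reported moments use the clinical sign conventions: internal knee and hip
extension positive, internal ankle plantarflexion positive.  Joint power is
moment times joint angular velocity, negative during eccentric absorption.
Moments and powers are amplitude-normalized to body mass (Nm/kg, W/kg) and
the vertical GRF to multiples of body weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .kinematics import JointSeries
from .model import GRAVITY, BodyModel
from .signal import derivative

COP_FOOT_SLACK_M = 0.10


class DynamicsError(ValueError):
    pass


@dataclass
class KineticsSeries:
    """Joint kinetics at the kinematic rate for one leg.

    ``moment`` maps joint -> internal moment in Nm (raw); ``moment_norm``
    the same in Nm/kg.  ``power``/``power_norm`` are attached by
    :func:`joint_power`.  ``grf_bw`` is the summed vertical GRF in body
    weights; ``reaction`` the proximal joint reaction forces in N.
    """

    rate: float
    mass: float
    moment: dict = field(default_factory=dict)
    moment_norm: dict = field(default_factory=dict)
    power: dict = field(default_factory=dict)
    power_norm: dict = field(default_factory=dict)
    reaction: dict = field(default_factory=dict)
    grf_bw: np.ndarray | None = None


def _cross_z(r: np.ndarray, f: np.ndarray) -> np.ndarray:
    return r[:, 0] * f[:, 1] - r[:, 1] * f[:, 0]


def _unwrapped_angle(prox: np.ndarray, dist: np.ndarray) -> np.ndarray:
    d = dist - prox
    return np.unwrap(np.arctan2(d[:, 1], d[:, 0]))


def newton_euler_planar(markers: dict, plate: np.ndarray, model: BodyModel,
                        rate: float, side: str = "R",
                        total_grf_bw: np.ndarray | None = None,
                        gravity: float = GRAVITY,
                        check_cop: bool = True) -> KineticsSeries:
    """Ankle, knee, and hip internal moments for one leg.

    Parameters
    ----------
    markers : filtered marker dict, (n, 3) arrays in metres.
    plate : (n, 3) array of (Fx, Fy, COPx) for this leg's plate, already
        filtered and resampled to the kinematic rate.
    total_grf_bw : optional summed-plates vertical force (N) at the
        kinematic rate, stored as body-weight multiples for reporting.
    """
    m = model.subject.mass
    segs = model.segments
    g_vec = np.array([0.0, -gravity])
    xy = {k: markers[f"{side}_{k}"][:, :2] for k in
          ("TOE", "HEEL", "ANK", "KNEE", "HIP")}
    n = xy["TOE"].shape[0]
    if plate.shape[0] != n:
        raise DynamicsError(
            f"plate stream length {plate.shape[0]} does not match the "
            f"{n}-frame kinematic stream; resample first")

    grf = plate[:, :2].copy()
    cop = np.column_stack([plate[:, 2], np.zeros(n)])

    if check_cop:
        loaded = plate[:, 1] > 0.2 * m * gravity
        if loaded.any():
            lo = np.minimum(xy["HEEL"][:, 0], xy["TOE"][:, 0]) - COP_FOOT_SLACK_M
            hi = np.maximum(xy["HEEL"][:, 0], xy["TOE"][:, 0]) + COP_FOOT_SLACK_M
            bad = loaded & ((cop[:, 0] < lo) | (cop[:, 0] > hi))
            if bad.any():
                warnings.warn(
                    f"COP falls > {COP_FOOT_SLACK_M * 100:.0f} cm outside the "
                    f"foot bounding box in {int(bad.sum())} loaded frames",
                    stacklevel=2)

    chain = (
        ("foot", xy["HEEL"], xy["TOE"], xy["ANK"]),
        ("shank", xy["KNEE"], xy["ANK"], xy["KNEE"]),
        ("thigh", xy["HIP"], xy["KNEE"], xy["HIP"]),
    )
    out = KineticsSeries(rate=rate, mass=m)
    dist_force = grf       # load applied ON the current segment, distal end
    dist_point = cop
    dist_moment = np.zeros(n)
    raw = {}
    for name, prox_m, dist_m, joint_m in chain:
        seg = segs[name]
        com = prox_m + seg["com_fraction"] * (dist_m - prox_m)
        acc = derivative(com, rate, order=2, axis=0)
        alpha = derivative(_unwrapped_angle(prox_m, dist_m), rate, order=2)
        react = seg["mass"] * (acc - g_vec) - dist_force
        mom = (seg["inertia"] * alpha
               - dist_moment
               - _cross_z(dist_point - com, dist_force)
               - _cross_z(joint_m - com, react))
        # `mom` is the net moment exerted ON this segment AT its proximal
        # joint; the next (proximal) segment receives the reactions
        raw[name] = (react, mom, joint_m)
        dist_force = -react
        dist_moment = -mom
        dist_point = joint_m

    # clinical signs: plantarflexion = clockwise on the foot; extension =
    # counter-clockwise on the shank (knee) / clockwise on the thigh (hip)
    out.moment = {
        "ankle": -raw["foot"][1],
        "knee": raw["shank"][1],
        "hip": -raw["thigh"][1],
    }
    out.reaction = {
        "ankle": raw["foot"][0],
        "knee": raw["shank"][0],
        "hip": raw["thigh"][0],
    }
    out.moment_norm = {j: v / m for j, v in out.moment.items()}
    if total_grf_bw is not None:
        out.grf_bw = np.asarray(total_grf_bw, dtype=float) / (m * gravity)
    return out


def joint_power(kinetics: KineticsSeries, joints: JointSeries) -> KineticsSeries:
    """Attach joint powers: P_j = -M_j * theta_dot_j (rad/s).

    With extension/plantarflexion moments positive and flexion/dorsiflexion
    angles positive, an extensor moment resisting flexion yields negative
    power (eccentric absorption) and extension against the same moment
    positive power (generation).
    """
    if not joints.velocity:
        raise DynamicsError("joint velocities required; run angular_velocity first")
    for j, mom in kinetics.moment.items():
        omega = np.deg2rad(joints.velocity[j])
        if omega.shape != mom.shape:
            raise DynamicsError(f"length mismatch between moment and velocity for {j}")
        kinetics.power[j] = -mom * omega
        kinetics.power_norm[j] = kinetics.power[j] / kinetics.mass
    return kinetics
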