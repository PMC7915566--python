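"""Synthetic drop-vertical-jump trials and muscle-damage indicator panels.

The generator stands in for an optical motion-capture + force-plate session.
A trial runs through six phases: a standing hold on the drop platform, the
ballistic drop, the landing (touchdown to peak knee flexion), the propulsion
(to take-off), a flight-phase relaxation, and a frozen flight hold.  Marker
positions follow from planar forward kinematics with the toe pinned to the
ground during contact, and the ground reaction force is derived from the
whole-body CoM acceleration, F = m (g + a_com), so every noise-free trial is
dynamically self-consistent by construction: the contact-phase net vertical
impulse equals the whole-body momentum change.

Each contact phase is built as a time-warped geometric pose path:

* the joint angles travel along the straight segment in angle space between
  the phase's end poses (touchdown -> peak flexion -> take-off), which makes
  the prescribed touchdown and peak angles exact and overshoot impossible;
* a prescribed degree-7 CoM-height profile fixes the timing: it descends
  from the touchdown height at the ballistic entry speed sqrt(2 g h_drop),
  stops at the peak-flexion height, and rises to take-off at the speed that
  realizes the prescribed jump height; the GRF implied by the profile is
  zero at touchdown and take-off and positive in between;
* the monotone time-warp xi(t) is recovered by inverting the (strictly
  monotone) CoM height along the pose path, so the chain reproduces the
  profile exactly.

The take-off speed is solved iteratively because the pelvis-to-CoM offset
changes while the pose relaxes in flight.  Condition presets parameterize
the touchdown/peak angles, phase durations, and jump height; the two bundled
presets encode the pre-exercise and 48-h post-exercise group means of the
study population this package emulates, with the reported between-subject
SDs available for cohort sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .io import TrialRecording
from .model import GRAVITY, BodyModel, SubjectSpec, build_body_model, forward_kinematics

RATE_KIN = 200.0
RATE_FORCE = 1000.0

#: default optical / force-plate noise (SD per frame per channel)
MARKER_NOISE_SD_M = 0.0005
FORCE_NOISE_SD_N = 2.0

_JOINT_ORDER = ("pelvis", "hip", "knee", "ankle")

#: reference population for sampling subjects (regional-level athletes)
POPULATION_MASS_KG = (78.9, 8.5)
POPULATION_HEIGHT_M = (1.811, 0.063)

DEFAULT_SUBJECT = dict(mass=78.9, height=1.811)

#: GRF must clear the event threshold by this margin over the contact
#: interior (edges excluded) for a plan to be accepted
_GRF_INTERIOR_MIN_N = 10.5
_GRF_EDGE_S = 0.006


class InfeasibleTrialError(ValueError):
    """The prescribed condition cannot be realized as a physical trial."""


@dataclass(frozen=True)
class ConditionParams:
    """One DVJ condition: angles in deg, durations in ms, jump height in cm.

    ``impact_jerk`` (m/s^3) sets how sharply the vertical GRF builds after
    touchdown (and decays before take-off); it is the generator's free
    impact-sharpness parameter.
    """

    drop_height: float = 0.30
    knee_flexion_ic: float = 41.61
    peak_knee_flexion: float = 84.15
    hip_flexion_ic: float = 43.39
    peak_hip_flexion: float = 61.18
    pelvic_tilt_ic: float = 17.31
    peak_pelvic_tilt: float = 19.74
    ankle_ic: float = -4.07
    peak_ankle: float = 37.69
    landing_duration: float = 134.4
    propulsion_duration: float = 178.8
    jump_height: float = 33.38
    marker_noise_sd: float = MARKER_NOISE_SD_M
    force_noise_sd: float = FORCE_NOISE_SD_N
    seed: int = 0
    impact_jerk: float = 500.0
    # take-off configuration (extended, plantarflexed push-off) and the
    # relaxed mid-flight pose; not condition-specific.
    takeoff_knee: float = 30.0
    takeoff_hip: float = 18.0
    takeoff_ankle: float = -15.0
    flight_knee: float = 35.0
    flight_hip: float = 22.0
    flight_ankle: float = -5.0

    def __post_init__(self):
        if self.drop_height <= 0:
            raise InfeasibleTrialError("drop_height must be > 0")
        if self.landing_duration <= 0 or self.propulsion_duration <= 0:
            raise InfeasibleTrialError("phase durations must be > 0")
        if self.marker_noise_sd < 0 or self.force_noise_sd < 0:
            raise InfeasibleTrialError("noise SDs must be >= 0")
        for name, ic, pk in (
            ("knee", self.knee_flexion_ic, self.peak_knee_flexion),
            ("hip", self.hip_flexion_ic, self.peak_hip_flexion),
            ("pelvis", self.pelvic_tilt_ic, self.peak_pelvic_tilt),
        ):
            if pk < ic:
                raise InfeasibleTrialError(
                    f"peak {name} angle ({pk}) must be >= its touchdown "
                    f"value ({ic})")

    def angles_ic(self):
        return np.array([self.pelvic_tilt_ic, self.hip_flexion_ic,
                         self.knee_flexion_ic, self.ankle_ic])

    def angles_peak(self):
        return np.array([self.peak_pelvic_tilt, self.peak_hip_flexion,
                         self.peak_knee_flexion, self.peak_ankle])

    def angles_takeoff(self):
        return np.array([self.pelvic_tilt_ic, self.takeoff_hip,
                         self.takeoff_knee, self.takeoff_ankle])

    def angles_flight(self):
        return np.array([self.pelvic_tilt_ic, self.flight_hip,
                         self.flight_knee, self.flight_ankle])


#: condition presets: group means of the emulated study (pre-exercise
#: baseline and 48 h after eccentric exercise of the knee extensors).
PRESET_MEANS = {
    "baseline": dict(
        knee_flexion_ic=41.61, peak_knee_flexion=84.15,
        hip_flexion_ic=43.39, peak_hip_flexion=61.18,
        pelvic_tilt_ic=17.31, peak_pelvic_tilt=19.74,
        ankle_ic=-4.07, peak_ankle=37.69,
        landing_duration=134.4, propulsion_duration=178.8,
        jump_height=33.38,
    ),
    "damaged48h": dict(
        knee_flexion_ic=40.37, peak_knee_flexion=88.66,
        hip_flexion_ic=44.49, peak_hip_flexion=69.38,
        pelvic_tilt_ic=20.19, peak_pelvic_tilt=25.16,
        ankle_ic=-9.02, peak_ankle=35.51,
        landing_duration=173.3, propulsion_duration=208.4,
        jump_height=32.15,
    ),
}

#: between-subject SDs matching the preset means, for cohort sampling.
PRESET_SDS = {
    "baseline": dict(
        knee_flexion_ic=5.9, peak_knee_flexion=6.2,
        hip_flexion_ic=6.4, peak_hip_flexion=10.5,
        pelvic_tilt_ic=4.4, peak_pelvic_tilt=5.9,
        ankle_ic=8.6, peak_ankle=4.2,
        landing_duration=35.4, propulsion_duration=28.1,
        jump_height=1.21,
    ),
    "damaged48h": dict(
        knee_flexion_ic=7.4, peak_knee_flexion=6.9,
        hip_flexion_ic=7.5, peak_hip_flexion=10.3,
        pelvic_tilt_ic=7.8, peak_pelvic_tilt=6.9,
        ankle_ic=6.7, peak_ankle=3.1,
        landing_duration=44.1, propulsion_duration=35.7,
        jump_height=1.4,
    ),
}


def preset(name: str, **overrides) -> ConditionParams:
    """Named condition preset (``baseline`` or ``damaged48h``)."""
    try:
        means = PRESET_MEANS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid presets: "
            f"{sorted(PRESET_MEANS)}") from None
    return ConditionParams(**{**means, **overrides})


# ---------------------------------------------------------------------------
# piecewise trajectory machinery
# ---------------------------------------------------------------------------

def _hermite_coeffs(T: float, rows0, rows1) -> np.ndarray:
    """Minimal-degree polynomial on [0, T] matching the given derivative
    rows (position, velocity, ...) at 0 and at T.  Rows may be scalars or
    length-4 vectors; the result has shape (n,) or (n, 4)."""
    rows0 = [np.asarray(r, dtype=float) for r in rows0]
    rows1 = [np.asarray(r, dtype=float) for r in rows1]
    n = len(rows0) + len(rows1)
    M = np.zeros((n, n))
    rhs = np.zeros((n,) + rows0[0].shape)
    r = 0
    for d, row in enumerate(rows0):
        M[r, d] = math.factorial(d)
        rhs[r] = row
        r += 1
    for d, row in enumerate(rows1):
        for j in range(d, n):
            M[r, j] = math.factorial(j) / math.factorial(j - d) * T ** (j - d)
        rhs[r] = row
        r += 1
    return np.linalg.solve(M, rhs)


class _PolySegment:
    def __init__(self, t0, t1, coeffs):
        self.t0, self.t1 = t0, t1
        c = np.atleast_2d(np.asarray(coeffs, dtype=float))
        if c.shape[1] != 4:
            c = np.tile(c.reshape(-1, 1), (1, 4))
        self._ders = [c]

    def _c(self, der):
        while len(self._ders) <= der:
            self._ders.append(
                np.polynomial.polynomial.polyder(self._ders[-1], axis=0))
        return self._ders[der]

    def __call__(self, t, der=0):
        return np.polynomial.polynomial.polyval(
            t - self.t0, self._c(der), tensor=True)


class _WarpSegment:
    """Quadratic pose path th(xi) = th0 + xi*dth + xi(1-xi)*bend, timed so
    the chain's CoM height follows the prescribed polynomial profile.

    With |bend_i| < |dth_i| every joint moves monotonically from th0 to
    th0 + dth, so the prescribed end poses are exact and overshoot is
    impossible; the bend only redistributes CoM leverage along the path.
    """

    def __init__(self, t0, t1, th0, dth, bend, y_coeffs, inverse_map):
        self.t0, self.t1 = t0, t1
        self.th0 = np.asarray(th0, dtype=float)
        self.dth = np.asarray(dth, dtype=float)
        self.bend = np.asarray(bend, dtype=float)
        self._y = [np.asarray(y_coeffs, dtype=float)]
        self._inv = inverse_map       # CubicSpline: com height -> xi

    def _yc(self, der):
        while len(self._y) <= der:
            self._y.append(np.polynomial.polynomial.polyder(self._y[-1]))
        return self._y[der]

    def xi(self, t, der=0):
        x = t - self.t0
        y = np.polynomial.polynomial.polyval(x, self._yc(0))
        y = np.clip(y, self._inv.x[0], self._inv.x[-1])
        if der == 0:
            return self._inv(y)
        dy = np.polynomial.polynomial.polyval(x, self._yc(1))
        if der == 1:
            return self._inv(y, 1) * dy
        ddy = np.polynomial.polynomial.polyval(x, self._yc(2))
        if der == 2:
            return self._inv(y, 2) * dy**2 + self._inv(y, 1) * ddy
        raise ValueError("warp segments support derivatives up to 2")

    def pose(self, xi, der=0):
        """th(xi) (deg, shape (4, n)) or its xi-derivatives."""
        xi = np.atleast_1d(xi)
        if der == 0:
            return (self.th0[:, None] + np.outer(self.dth, xi)
                    + np.outer(self.bend, xi * (1 - xi)))
        if der == 1:
            return self.dth[:, None] + np.outer(self.bend, 1 - 2 * xi)
        if der == 2:
            return np.tile(-2 * self.bend[:, None], (1, len(xi)))
        raise ValueError("pose derivatives supported up to 2")

    def __call__(self, t, der=0):
        xi = self.xi(t, 0)
        if der == 0:
            return self.pose(xi)
        dxi = self.xi(t, 1)
        if der == 1:
            return self.pose(xi, 1) * dxi
        if der == 2:
            return (self.pose(xi, 1) * self.xi(t, 2)
                    + self.pose(xi, 2) * dxi**2)
        raise ValueError("warp segments support derivatives up to 2")


class AngleTrajectory:
    """Piecewise joint-angle plan: angle(t) in deg for the 4 sagittal DoF."""

    def __init__(self):
        self.segments = []

    def add(self, seg):
        if self.segments and abs(seg.t0 - self.segments[-1].t1) > 1e-12:
            raise ValueError("trajectory segments must be contiguous")
        self.segments.append(seg)

    def add_poly(self, t0, t1, coeffs):
        self.add(_PolySegment(t0, t1, coeffs))

    def add_hold(self, t0, t1, angles):
        self.add(_PolySegment(t0, t1, np.asarray(angles, dtype=float)[None, :]))

    @property
    def t_end(self):
        return self.segments[-1].t1

    def __call__(self, t, der: int = 0) -> np.ndarray:
        """Angles (deg) or their der-th time derivative, shape (4, n)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        starts = np.array([s.t0 for s in self.segments])
        idx = np.clip(np.searchsorted(starts, t, side="right") - 1,
                      0, len(starts) - 1)
        out = np.empty((4, t.size))
        for i, seg in enumerate(self.segments):
            mask = idx == i
            if mask.any():
                out[:, mask] = seg(np.clip(t[mask], seg.t0, seg.t1), der)
        return out


# ---------------------------------------------------------------------------
# contact-phase construction
# ---------------------------------------------------------------------------

_XI_GRID = np.linspace(0.0, 1.0, 801)


#: minimum |d com_y / d xi| (m) required at both ends of a contact pose
#: path; below this the time warp would demand unbounded joint velocities
_MIN_END_LEVERAGE = 0.05

_XI_COARSE = np.linspace(0.0, 1.0, 161)


def _path_bend(th0, th1, subject, model, toe_anchor):
    """Quadratic bend (deg) that balances the CoM leverage |d com_y / d xi|
    between the two ends of the pose path, keeping every joint monotone.

    The warp converts CoM speed into joint speed by 1/leverage, so a weak
    end would concentrate joint velocity (and high-frequency content)
    there.  The bend magnitude is chosen by a 1-D search maximizing the
    smaller of the two end slopes over the monotone candidates.
    """
    d = np.deg2rad(th1 - th0)
    J0 = _com_jacobian(th0, subject, model, toe_anchor)[1]
    J1 = _com_jacobian(th1, subject, model, toe_anchor)[1]
    sgn = math.copysign(1.0, float(J0 @ d) + float(J1 @ d))
    w = sgn * np.sign((J0 + J1) / 2) * np.abs(d)
    lim = 0.8 * np.abs(th1 - th0)
    best_bend = np.zeros(4)
    best_score = -np.inf
    for gamma in np.linspace(-0.8, 0.8, 17):
        bend = np.clip(np.rad2deg(gamma * w), -lim, lim)
        ang = (th0[:, None] + _XI_COARSE[None, :] * (th1 - th0)[:, None]
               + (_XI_COARSE * (1 - _XI_COARSE))[None, :] * bend[:, None])
        gy = forward_kinematics(ang, subject, model,
                                toe_anchor=toe_anchor)["com"][1]
        dg = np.diff(gy)
        if not ((dg > 0).all() or (dg < 0).all()):
            continue
        n = len(_XI_COARSE) - 1
        score = min(abs(dg[0]), abs(dg[-1])) * n
        if score > best_score:
            best_score = score
            best_bend = bend
    return best_bend


def _pose_path_com(th0, th1, bend, subject, model, toe_anchor):
    """CoM height along the (bent) pose path, sampled on the xi grid."""
    ang = (th0[:, None] + _XI_GRID[None, :] * (th1 - th0)[:, None]
           + (_XI_GRID * (1 - _XI_GRID))[None, :] * np.asarray(bend)[:, None])
    fk = forward_kinematics(ang, subject, model, toe_anchor=toe_anchor)
    return fk["com"][1]


def _inverse_map(g_samples):
    """CubicSpline mapping CoM height -> xi; requires strict monotonicity
    and a minimum CoM leverage at both ends of the path."""
    d = np.diff(g_samples)
    if not ((d < 0).all() or (d > 0).all()):
        raise InfeasibleTrialError(
            "CoM height is not monotone along the pose path; the prescribed "
            "poses cannot be timed consistently")
    n = len(_XI_GRID) - 1
    if min(abs(d[0]), abs(d[-1])) * n < _MIN_END_LEVERAGE:
        raise InfeasibleTrialError(
            "pose path gives insufficient CoM leverage at a phase boundary; "
            "the prescribed postures are too close in CoM height")
    if (d < 0).all():
        return CubicSpline(g_samples[::-1], _XI_GRID[::-1])
    return CubicSpline(g_samples, _XI_GRID)


#: a GRF excursion below the event threshold is tolerated mid-phase if it
#: is shorter than this (safely under the 20 ms event-detector debounce)
#: and does not pull on the ground harder than _GRF_DIP_FLOOR_N
_GRF_DIP_MAX_S = 0.015
_GRF_DIP_FLOOR_N = -300.0


def _check_profile(y_coeffs, T, mass, descending, label):
    """The CoM profile must keep the implied GRF workable and move
    monotonically toward the target height.

    The GRF may dip below the 10 N event threshold mid-phase only briefly
    (shorter than the detector's debounce window, so event timing is
    unaffected) and never strongly negative.
    """
    dt = 2e-4
    t = np.arange(0.0, T + dt / 2, dt)
    acc = np.polynomial.polynomial.polyval(
        t, np.polynomial.polynomial.polyder(y_coeffs, 2))
    F = mass * (GRAVITY + acc)
    inner = (t > _GRF_EDGE_S) & (t < T - _GRF_EDGE_S)
    if inner.any():
        if F[inner].min() < _GRF_DIP_FLOOR_N:
            raise InfeasibleTrialError(
                f"{label}: implied GRF reaches {F[inner].min():.0f} N "
                f"mid-phase; the phase duration is too long for the "
                f"prescribed postures (CoM would have to float)")
        run = _longest_run(F[inner] < _GRF_INTERIOR_MIN_N) * dt
        if run > _GRF_DIP_MAX_S:
            raise InfeasibleTrialError(
                f"{label}: implied GRF stays below the event threshold for "
                f"{run * 1e3:.0f} ms mid-phase; the contact would be "
                f"detected as broken")
    vel = np.polynomial.polynomial.polyval(
        t, np.polynomial.polynomial.polyder(y_coeffs, 1))
    sgn = -1.0 if descending else 1.0
    if (sgn * vel[1:-1] < -1e-9).any():
        raise InfeasibleTrialError(
            f"{label}: CoM profile is not monotone; the phase duration is "
            f"too short for the required momentum change")


@dataclass
class TrialPlan:
    """Everything the generator decided for one trial (exposed for tests)."""

    subject: SubjectSpec
    model: BodyModel
    params: ConditionParams
    trajectory: AngleTrajectory
    t_release: float
    t_ic: float
    t_peak: float
    t_takeoff: float
    t_end: float
    v_in: float
    v_out: float
    com_ic: np.ndarray
    com_takeoff: np.ndarray
    com_vel_ic: np.ndarray
    com_vel_takeoff: np.ndarray
    pelvis_static_y: float
    toe_anchor: float

    def com_path(self, t) -> np.ndarray:
        """Whole-body CoM (2, n): forward kinematics during contact,
        ballistic during flight, frozen while standing on the platform."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        ang = self.trajectory(t)
        fk_com = forward_kinematics(ang, self.subject, self.model,
                                    toe_anchor=self.toe_anchor)["com"]
        out = np.array(fk_com)
        g = GRAVITY
        pre = t < self.t_ic
        dt = t[pre] - self.t_ic
        dt = np.maximum(dt, self.t_release - self.t_ic)  # frozen on platform
        out[0, pre] = self.com_ic[0] + self.com_vel_ic[0] * dt
        out[1, pre] = (self.com_ic[1] + self.com_vel_ic[1] * dt
                       - 0.5 * g * dt**2)
        post = t >= self.t_takeoff
        dt = t[post] - self.t_takeoff
        out[0, post] = self.com_takeoff[0] + self.com_vel_takeoff[0] * dt
        out[1, post] = (self.com_takeoff[1] + self.com_vel_takeoff[1] * dt
                        - 0.5 * g * dt**2)
        return out


def plan_dvj_trial(subject: SubjectSpec, params: ConditionParams,
                   model: BodyModel | None = None) -> TrialPlan:
    """Solve the CoM profiles, time warps, and flight splines for one trial."""
    model = model or build_body_model(subject)
    g = GRAVITY
    m = subject.mass
    dt_kin = 1.0 / RATE_KIN
    T_land = params.landing_duration / 1e3
    T_prop = params.propulsion_duration / 1e3
    T_relax = 0.30
    T_flight = 0.40
    hold = 0.10
    toe_anchor = 0.15
    jerk = params.impact_jerk

    th_ic = params.angles_ic()
    th_pk = params.angles_peak()
    th_to = params.angles_takeoff()
    th_fl = params.angles_flight()

    v_in = math.sqrt(2 * g * params.drop_height)
    t_drop = math.sqrt(2 * params.drop_height / g)
    t_ic = math.ceil((hold + t_drop) / dt_kin - 1e-9) * dt_kin
    t_release = t_ic - t_drop
    t_peak = t_ic + T_land
    t_to = t_peak + T_prop
    t_end = t_to + T_flight

    fk = {lbl: forward_kinematics(th, subject, model, toe_anchor=toe_anchor)
          for lbl, th in (("ic", th_ic), ("pk", th_pk), ("to", th_to),
                          ("static", np.zeros(4)))}
    y_ic, y_pk, y_to = (fk[k]["com"][1] for k in ("ic", "pk", "to"))

    # --- landing: touchdown -> peak flexion ---------------------------------
    bend_land = _path_bend(th_ic, th_pk, subject, model, toe_anchor)
    try:
        g_land = _pose_path_com(th_ic, th_pk, bend_land, subject, model,
                                toe_anchor)
        inv_land = _inverse_map(g_land)
    except InfeasibleTrialError:
        bend_land = np.zeros(4)
        g_land = _pose_path_com(th_ic, th_pk, bend_land, subject, model,
                                toe_anchor)
        inv_land = _inverse_map(g_land)
    y_land = _hermite_coeffs(T_land, [y_ic, -v_in, -g, jerk],
                             [y_pk, 0.0, 0.0, 0.0])
    _check_profile(y_land, T_land, m, descending=True, label="landing phase")
    land_seg = _WarpSegment(t_ic, t_peak, th_ic, th_pk - th_ic, bend_land,
                            y_land, inv_land)

    # --- propulsion: peak flexion -> take-off (v_out iterated) --------------
    pelvis_static_y = fk["static"]["pelvis_centroid"][1]
    target_apex = pelvis_static_y + params.jump_height / 100.0
    pelvis_to_y = fk["to"]["pelvis_centroid"][1]
    if target_apex <= pelvis_to_y + 1e-4:
        raise InfeasibleTrialError(
            f"prescribed jump height {params.jump_height} cm places the "
            f"apex below the take-off pelvis height")
    bend_prop = _path_bend(th_pk, th_to, subject, model, toe_anchor)
    try:
        g_prop = _pose_path_com(th_pk, th_to, bend_prop, subject, model,
                                toe_anchor)
        inv_prop = _inverse_map(g_prop)
    except InfeasibleTrialError:
        bend_prop = np.zeros(4)
        g_prop = _pose_path_com(th_pk, th_to, bend_prop, subject, model,
                                toe_anchor)
        inv_prop = _inverse_map(g_prop)
    com_to = fk["to"]["com"]

    t_fine = np.arange(0.0, T_flight + 1e-9, 1e-3)

    def propulsion_profile(v):
        """One or two CoM profile pieces covering [t_peak, t_to].

        A long propulsion (slower than the polynomial family's feasible
        tempo) is split into a slow early rise near the deep posture (GRF
        ~ body weight) followed by a standard-tempo push, joined with C^3
        continuity.  Returns a list of warp segments.
        """
        dy = y_to - y_pk
        T_push = _KAPPA_SPLIT * dy / v
        if T_prop <= T_push + 0.02:
            y_coeffs = _hermite_coeffs(T_prop, [y_pk, 0.0, 0.0, 0.0],
                                       [y_to, v, -g, -jerk])
            return [_WarpSegment(t_peak, t_to, th_pk, th_to - th_pk,
                                 bend_prop, y_coeffs, inv_prop)]
        T_a = T_prop - T_push
        delta = 0.08 * dy
        v_a = 1.5 * delta / T_a
        y_a = _hermite_coeffs(T_a, [y_pk, 0.0, 0.0, 0.0],
                              [y_pk + delta, v_a, 0.0, 0.0])
        y_b = _hermite_coeffs(T_push, [y_pk + delta, v_a, 0.0, 0.0],
                              [y_to, v, -g, -jerk])
        t_mid = t_peak + T_a
        return [
            _WarpSegment(t_peak, t_mid, th_pk, th_to - th_pk,
                         bend_prop, y_a, inv_prop),
            _WarpSegment(t_mid, t_to, th_pk, th_to - th_pk,
                         bend_prop, y_b, inv_prop),
        ]

    def solve_takeoff(th_flight):
        v = math.sqrt(2 * g * (target_apex - pelvis_to_y))
        for _ in range(80):
            segs = propulsion_profile(v)
            seg = segs[-1]
            vel_to = seg(np.array([t_to]), 1)[:, 0]
            acc_to = seg(np.array([t_to]), 2)[:, 0]
            relax = _hermite_coeffs(
                T_relax, [th_to, vel_to, acc_to],
                [th_flight, np.zeros(4), np.zeros(4)])
            in_relax = t_fine < T_relax
            ang_f = np.empty((4, t_fine.size))
            ang_f[:, in_relax] = np.polynomial.polynomial.polyval(
                t_fine[in_relax], relax, tensor=True)
            ang_f[:, ~in_relax] = th_flight[:, None]
            fk_f = forward_kinematics(ang_f, subject, model)
            offset = fk_f["pelvis_centroid"][1] - fk_f["com"][1]
            y_pel = com_to[1] + v * t_fine - 0.5 * g * t_fine**2 + offset
            i_star = int(np.argmax(y_pel))
            t_star = max(t_fine[i_star], 1e-2)
            v_new = (target_apex - com_to[1] - offset[i_star]
                     + 0.5 * g * t_star**2) / t_star
            if v_new <= 0:
                return None
            converged = abs(v_new - v) < 1e-11
            v = v_new
            if converged:
                break
        return v, segs, relax

    solution = solve_takeoff(th_fl)
    if solution is None:
        # flight pose relaxation raises the pelvis past the apex target;
        # keep the take-off pose through the flight instead
        th_fl = th_to.copy()
        solution = solve_takeoff(th_fl)
    if solution is None:
        raise InfeasibleTrialError(
            "jump height unreachable from the take-off configuration")
    v_out, prop_segs, relax_coeffs = solution
    vel_to = prop_segs[-1](np.array([t_to]), 1)[:, 0]
    for seg in prop_segs:
        _check_profile(seg._y[0], seg.t1 - seg.t0, m, descending=False,
                       label="propulsion phase")

    # --- drop and flight splines --------------------------------------------
    vel_ic = land_seg(np.array([t_ic]), 1)[:, 0]
    acc_ic = land_seg(np.array([t_ic]), 2)[:, 0]
    th_start = th_ic - vel_ic * t_drop * 0.3
    th_start[2] = max(th_start[2], 2.0)   # keep the knee off hyperextension
    th_start[1] = max(th_start[1], 0.0)
    drop_coeffs = _hermite_coeffs(
        t_drop, [th_start, np.zeros(4), np.zeros(4)], [th_ic, vel_ic, acc_ic])

    traj = AngleTrajectory()
    traj.add_hold(0.0, t_release, th_start)
    traj.add_poly(t_release, t_ic, drop_coeffs)
    traj.add(land_seg)
    for seg in prop_segs:
        traj.add(seg)
    traj.add_poly(t_to, t_to + T_relax, relax_coeffs)
    traj.add_hold(t_to + T_relax, t_end, th_fl)

    # CoM boundary velocities: horizontal from the pose-path rate, vertical
    # pinned to the ballistic values so impulse-momentum closes exactly
    J_ic = _com_jacobian(th_ic, subject, model, toe_anchor)
    J_to = _com_jacobian(th_to, subject, model, toe_anchor)
    com_vel_ic = np.array([float(J_ic[0] @ np.deg2rad(vel_ic)), -v_in])
    com_vel_to = np.array([float(J_to[0] @ np.deg2rad(vel_to)), v_out])

    plan = TrialPlan(
        subject=subject, model=model, params=params, trajectory=traj,
        t_release=t_release, t_ic=t_ic, t_peak=t_peak, t_takeoff=t_to,
        t_end=t_end, v_in=v_in, v_out=v_out, com_ic=fk["ic"]["com"],
        com_takeoff=com_to, com_vel_ic=com_vel_ic,
        com_vel_takeoff=com_vel_to, pelvis_static_y=pelvis_static_y,
        toe_anchor=toe_anchor)
    _check_plan(plan)
    return plan


_FD_ANGLE_STEP_DEG = 0.01


def _com_jacobian(angles_deg, subject, model, toe_anchor=0.0):
    """d(CoM)/d(angle in rad), shape (2, 4), by central differences."""
    J = np.empty((2, 4))
    for j in range(4):
        up = np.array(angles_deg, dtype=float)
        dn = np.array(angles_deg, dtype=float)
        up[j] += _FD_ANGLE_STEP_DEG
        dn[j] -= _FD_ANGLE_STEP_DEG
        p1 = forward_kinematics(up, subject, model, toe_anchor=toe_anchor)["com"]
        p0 = forward_kinematics(dn, subject, model, toe_anchor=toe_anchor)["com"]
        J[:, j] = (p1 - p0) / (2 * math.radians(_FD_ANGLE_STEP_DEG))
    return J


def _check_plan(plan: TrialPlan):
    """Validate the assembled plan end to end on the force grid."""
    p = plan.params
    t = np.linspace(plan.t_ic, plan.t_takeoff, 400)
    ang = plan.trajectory(t)
    peaks = p.angles_peak()
    if ang[2].max() > peaks[2] + 1e-6:
        raise InfeasibleTrialError(
            f"knee trajectory exceeds the prescribed peak "
            f"({ang[2].max():.2f} > {peaks[2]:.2f} deg)")
    landing = t <= plan.t_peak
    for i, name in enumerate(_JOINT_ORDER):
        if ang[i, landing].max() > peaks[i] + 1e-6:
            raise InfeasibleTrialError(
                f"{name} trajectory overshoots its prescribed landing peak")
    t_f = np.arange(0.0, plan.t_end + 1e-9, 1.0 / RATE_FORCE)
    fy = _total_grf(plan, t_f)[1]
    neg = fy < -1e-6
    run = _longest_run(neg)
    if run / RATE_FORCE > 0.050:
        raise InfeasibleTrialError(
            f"implied vertical GRF is negative for {run} ms; the prescribed "
            f"phase durations are dynamically inconsistent")


def _longest_run(mask: np.ndarray) -> int:
    best = cur = 0
    for v in mask:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def _total_grf(plan: TrialPlan, t_force: np.ndarray) -> np.ndarray:
    """Noise-free total GRF (2, n): m (g + a_com) in contact, zero in flight."""
    com = plan.com_path(t_force)
    dt = float(t_force[1] - t_force[0])
    acc = np.empty_like(com)
    acc[:, 1:-1] = (com[:, 2:] - 2 * com[:, 1:-1] + com[:, :-2]) / dt**2
    acc[:, 0] = acc[:, 1]
    acc[:, -1] = acc[:, -2]
    m = plan.subject.mass
    f = m * (acc + np.array([[0.0], [GRAVITY]]))
    contact = (t_force >= plan.t_ic) & (t_force < plan.t_takeoff)
    f[:, ~contact] = 0.0
    return f


def _marker_set(plan: TrialPlan, t_kin: np.ndarray) -> dict:
    """Noise-free 3D marker trajectories on the kinematic grid."""
    subj = plan.subject
    ang = plan.trajectory(t_kin)
    fk = forward_kinematics(ang, subj, plan.model, toe_anchor=plan.toe_anchor)
    shift = plan.com_path(t_kin) - fk["com"]     # zero during contact
    z_hip = subj.length("hip_half_width")

    def as3d(key, z):
        p = fk[key] + shift
        return np.column_stack([p[0], p[1], np.full(p.shape[1], z)])

    markers = {}
    for side, z in (("R", z_hip), ("L", -z_hip)):
        markers[f"{side}_TOE"] = as3d("toe", z)
        markers[f"{side}_HEEL"] = as3d("heel", z)
        markers[f"{side}_ANK"] = as3d("ankle", z)
        markers[f"{side}_KNEE"] = as3d("knee", z)
        markers[f"{side}_HIP"] = as3d("hip", z)
    markers["RASI"] = as3d("asis", 0.6 * z_hip)
    markers["LASI"] = as3d("asis", -0.6 * z_hip)
    markers["RPSI"] = as3d("psis", 0.6 * z_hip)
    markers["LPSI"] = as3d("psis", -0.6 * z_hip)
    return markers


def generate_dvj_trial(subject: SubjectSpec, params: ConditionParams,
                       model: BodyModel | None = None) -> TrialRecording:
    """One synthetic DVJ trial: markers at 200 Hz, two plates at 1000 Hz."""
    plan = plan_dvj_trial(subject, params, model)
    rng = np.random.default_rng(params.seed)

    n_kin = int(math.floor(plan.t_end * RATE_KIN + 1e-9)) + 1
    n_force = n_kin * int(RATE_FORCE / RATE_KIN)
    t_kin = np.arange(n_kin) / RATE_KIN
    t_force = np.arange(n_force) / RATE_FORCE

    markers = _marker_set(plan, t_kin)
    f_total = _total_grf(plan, t_force)

    # COP sweeps from the rear quarter toward the toe across the contact
    ang_f = plan.trajectory(t_force)
    fk_f = forward_kinematics(ang_f, plan.subject, plan.model,
                              toe_anchor=plan.toe_anchor)
    foot_lo = np.minimum(fk_f["heel"][0], fk_f["toe"][0])
    foot_hi = np.maximum(fk_f["heel"][0], fk_f["toe"][0])
    w = np.clip((t_force - plan.t_ic) / (plan.t_takeoff - plan.t_ic), 0, 1)
    cop = foot_lo + (0.25 + 0.6 * w) * (foot_hi - foot_lo)

    plates = {}
    for pid in ("R", "L"):
        plate = np.column_stack([0.5 * f_total[0], 0.5 * f_total[1], cop])
        if params.force_noise_sd > 0:
            plate[:, :2] += rng.normal(0, params.force_noise_sd,
                                       size=(n_force, 2))
        plates[pid] = plate
    if params.marker_noise_sd > 0:
        for lab in markers:
            markers[lab] = markers[lab] + rng.normal(
                0, params.marker_noise_sd, size=markers[lab].shape)

    return TrialRecording(
        markers=markers, plates=plates, subject=subject,
        rate_kin=RATE_KIN, rate_force=RATE_FORCE, trial_kind="dvj",
        meta={"plan": plan, "params": params})


def generate_static_trial(subject: SubjectSpec, duration: float = 1.2,
                          marker_noise_sd: float = MARKER_NOISE_SD_M,
                          force_noise_sd: float = FORCE_NOISE_SD_N,
                          seed: int = 0,
                          model: BodyModel | None = None) -> TrialRecording:
    """Neutral standing reference trial (all joint angles at zero)."""
    model = model or build_body_model(subject)
    rng = np.random.default_rng(seed)
    n_kin = int(round(duration * RATE_KIN))
    n_force = n_kin * int(RATE_FORCE / RATE_KIN)
    fk = forward_kinematics(np.zeros(4), subject, model, toe_anchor=0.15)
    z_hip = subject.length("hip_half_width")

    def as3d(key, z):
        p = fk[key]
        return np.tile([p[0], p[1], z], (n_kin, 1))

    markers = {}
    for side, z in (("R", z_hip), ("L", -z_hip)):
        for key, lab in (("toe", "TOE"), ("heel", "HEEL"), ("ankle", "ANK"),
                         ("knee", "KNEE"), ("hip", "HIP")):
            markers[f"{side}_{lab}"] = as3d(key, z)
    for lab, key, z in (("RASI", "asis", 0.6 * z_hip),
                        ("LASI", "asis", -0.6 * z_hip),
                        ("RPSI", "psis", 0.6 * z_hip),
                        ("LPSI", "psis", -0.6 * z_hip)):
        markers[lab] = as3d(key, z)

    half_weight = 0.5 * subject.mass * GRAVITY
    plates = {}
    for pid in ("R", "L"):
        plate = np.column_stack([
            np.zeros(n_force),
            np.full(n_force, half_weight),
            np.full(n_force, fk["com"][0]),
        ])
        if force_noise_sd > 0:
            plate[:, :2] += rng.normal(0, force_noise_sd, size=(n_force, 2))
        plates[pid] = plate
    if marker_noise_sd > 0:
        for lab in markers:
            markers[lab] = markers[lab] + rng.normal(
                0, marker_noise_sd, size=markers[lab].shape)
    return TrialRecording(
        markers=markers, plates=plates, subject=subject,
        rate_kin=RATE_KIN, rate_force=RATE_FORCE, trial_kind="static")


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

def sample_subject(rng: np.random.Generator) -> SubjectSpec:
    """Draw one subject from the reference athlete population."""
    mass = max(45.0, rng.normal(*POPULATION_MASS_KG))
    height = max(1.45, rng.normal(*POPULATION_HEIGHT_M))
    return SubjectSpec(mass=mass, height=height)


#: between-session (test-retest) correlation of each subject's biomechanical
#: parameters.  0.85 is typical of repeated drop-jump testing and puts the
#: implied paired effect sizes of the starred kinematic outcomes inside the
#: a-priori effect-size range (1.05-1.46) the emulated study design assumed.
SESSION_RHO = 0.85

#: feasible range of the dimensionless phase tempo kappa = v T / |delta
#: CoM| for the degree-7 contact profiles (with margin); cohort durations
#: are sampled as a tempo factor truncated to this window
_KAPPA_LANDING = (1.46, 2.14)
_KAPPA_PROP = (1.45, 2.15)

#: tempo of the push piece when a long propulsion is split into a slow
#: early rise plus a standard-tempo push
_KAPPA_SPLIT = 1.85

_JOINT_FIELDS = {
    "pelvis": ("pelvic_tilt_ic", "peak_pelvic_tilt"),
    "hip": ("hip_flexion_ic", "peak_hip_flexion"),
    "knee": ("knee_flexion_ic", "peak_knee_flexion"),
    "ankle": ("ankle_ic", "peak_ankle"),
}
def _phase_ratios(params: ConditionParams, subject: SubjectSpec,
                  model: BodyModel):
    """(landing, propulsion) values of |delta CoM| / v in seconds: the
    duration each phase would take at tempo kappa = 1."""
    fk = {lbl: forward_kinematics(th, subject, model, toe_anchor=0.15)
          for lbl, th in (("ic", params.angles_ic()),
                          ("pk", params.angles_peak()),
                          ("to", params.angles_takeoff()),
                          ("static", np.zeros(4)))}
    v_in = math.sqrt(2 * GRAVITY * params.drop_height)
    dy_land = fk["ic"]["com"][1] - fk["pk"]["com"][1]
    if dy_land <= 0.02:
        raise InfeasibleTrialError("sampled postures give no landing descent")
    apex = (fk["static"]["pelvis_centroid"][1] + params.jump_height / 100
            - fk["to"]["pelvis_centroid"][1])
    v_out = math.sqrt(2 * GRAVITY * max(apex, 0.02))
    dy_prop = max(fk["to"]["com"][1] - fk["pk"]["com"][1], 0.02)
    return dy_land / v_in, dy_prop / v_out


def ensure_feasible(subject: SubjectSpec, params: ConditionParams,
                    model: BodyModel | None = None) -> ConditionParams:
    """Return ``params``, with phase durations recentred in the feasible
    window if the original prescription cannot be planned.

    Sampled cohort conditions occasionally combine postures and durations
    that no physical CoM trajectory connects; pulling the durations to the
    middle of the feasible band preserves the sampled postures (the primary
    outcome variables) at the cost of a small duration shrinkage.
    """
    from dataclasses import asdict, replace
    model = model or build_body_model(subject)
    try:
        plan_dvj_trial(subject, params, model)
        return params
    except InfeasibleTrialError:
        pass
    r_land, r_prop = _phase_ratios(params, subject, model)
    adjusted = replace(
        params,
        landing_duration=sum(_KAPPA_LANDING) / 2 * r_land * 1e3,
        propulsion_duration=sum(_KAPPA_PROP) / 2 * r_prop * 1e3)
    plan_dvj_trial(subject, adjusted, model)   # raises if still infeasible
    return adjusted


def sample_paired_conditions(rng: np.random.Generator,
                             pre: str = "baseline",
                             post: str = "damaged48h",
                             rho: float = SESSION_RHO,
                             subject: SubjectSpec | None = None,
                             model: BodyModel | None = None,
                             seed_pair=(0, 1)) -> tuple:
    """Draw one subject's pre/post condition pair.

    Each joint's touchdown and peak angles share one standard-normal deviate
    per session (so peaks stay above touchdown values), each scalar field
    has its own; the pre and post deviates correlate at ``rho``.  When a
    subject is given, sampled durations are clamped to the feasible window
    of the sampled postures.
    """
    def correlated_pair():
        w1 = rng.normal()
        w2 = rho * w1 + math.sqrt(1 - rho**2) * rng.normal()
        return w1, w2

    fields = {0: {}, 1: {}}
    for joint, (f_ic, f_pk) in _JOINT_FIELDS.items():
        w = correlated_pair()
        for k, name in enumerate((pre, post)):
            fields[k][f_ic] = (PRESET_MEANS[name][f_ic]
                               + PRESET_SDS[name][f_ic] * w[k])
            fields[k][f_pk] = (PRESET_MEANS[name][f_pk]
                               + PRESET_SDS[name][f_pk] * w[k])
        if joint != "ankle":
            for k in (0, 1):
                fields[k][f_pk] = max(fields[k][f_pk], fields[k][f_ic] + 0.5)
    w = correlated_pair()
    for k, name in enumerate((pre, post)):
        v = (PRESET_MEANS[name]["jump_height"]
             + PRESET_SDS[name]["jump_height"] * w[k])
        fields[k]["jump_height"] = max(v, 5.0)

    if subject is None:
        # durations straight from the reference means/SDs (no feasibility
        # information without a subject)
        for f in ("landing_duration", "propulsion_duration"):
            w = correlated_pair()
            for k, name in enumerate((pre, post)):
                v = PRESET_MEANS[name][f] + PRESET_SDS[name][f] * w[k]
                fields[k][f] = max(v, 60.0)
        return tuple(ConditionParams(**fields[k], seed=int(seed_pair[k]))
                     for k in (0, 1))

    # durations are drawn from the reference statistics and then clamped
    # to the dynamically feasible tempo band implied by this subject's
    # sampled postures (kappa = v T / |delta CoM|)
    model = model or build_body_model(subject)
    w_land = correlated_pair()
    w_prop = correlated_pair()
    for k, name in enumerate((pre, post)):
        probe = ConditionParams(**fields[k],
                                landing_duration=100.0,
                                propulsion_duration=100.0)
        r_land, r_prop = _phase_ratios(probe, subject, model)
        t_land = (PRESET_MEANS[name]["landing_duration"]
                  + PRESET_SDS[name]["landing_duration"] * w_land[k])
        t_prop = (PRESET_MEANS[name]["propulsion_duration"]
                  + PRESET_SDS[name]["propulsion_duration"] * w_prop[k])
        fields[k]["landing_duration"] = float(np.clip(
            t_land, _KAPPA_LANDING[0] * r_land * 1e3,
            _KAPPA_LANDING[1] * r_land * 1e3))
        # long propulsions are always realizable (slow rise + push), so
        # only the fast side needs clamping
        fields[k]["propulsion_duration"] = float(
            max(t_prop, _KAPPA_PROP[0] * r_prop * 1e3))
    return tuple(ConditionParams(**fields[k], seed=int(seed_pair[k]))
                 for k in (0, 1))


def sample_feasible_paired_conditions(rng: np.random.Generator,
                                      subject: SubjectSpec,
                                      model: BodyModel | None = None,
                                      pre: str = "baseline",
                                      post: str = "damaged48h",
                                      rho: float = SESSION_RHO,
                                      seed_pair=(0, 1),
                                      max_tries: int = 25) -> tuple:
    """Rejection-sample a pre/post condition pair that the generator can
    realize for this subject.

    A few percent of unconstrained draws combine postures whose CoM
    geometry admits no physical contact trajectory; those draws are
    rejected and redrawn, which truncates the most extreme posture
    combinations the way real (necessarily feasible) coordination would.
    """
    model = model or build_body_model(subject)
    last_err = None
    for _ in range(max_tries):
        pair = sample_paired_conditions(rng, pre=pre, post=post, rho=rho,
                                        subject=subject, model=model,
                                        seed_pair=seed_pair)
        try:
            return tuple(ensure_feasible(subject, cp, model) for cp in pair)
        except InfeasibleTrialError as exc:
            last_err = exc
    raise InfeasibleTrialError(
        f"no feasible condition pair found in {max_tries} draws: {last_err}")


# ---------------------------------------------------------------------------
# muscle-damage indicator panels
# ---------------------------------------------------------------------------

#: per-timepoint (mean, SD) of the damage indicators in the emulated study:
#: isometric peak torque as % of baseline, serum creatine kinase in U/L,
#: and palpation soreness on the 0-10 scale.
EIMD_TIMEPOINTS = {
    "IPT_pct": [("0h", 100.0, 0.0), ("post", 75.4, 7.0),
                ("24h", 79.7, 10.6), ("48h", 80.5, 9.9)],
    "CK": [("0h", 202.0, 125.0), ("48h", 2040.0, 1306.0)],
    "DOMS": [("0h", 0.0, 0.0), ("24h", 5.5, 1.3), ("48h", 6.7, 1.6)],
}

_INDICATOR_BOUNDS = {"IPT_pct": (0.0, None), "CK": (0.0, None),
                     "DOMS": (0.0, 10.0)}


@dataclass(frozen=True)
class EIMDPanelParams:
    """Sampling plan for an indicator panel.

    ``timepoints`` maps indicator -> list of (label, mean, SD);
    ``subject_rho`` is the within-subject correlation across timepoints,
    induced by a shared subject random effect.
    """

    timepoints: dict = field(default_factory=lambda: dict(EIMD_TIMEPOINTS))
    n_subjects: int = 13
    subject_rho: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0 <= self.subject_rho < 1:
            raise ValueError("subject_rho must be in [0, 1)")
        for ind, rows in self.timepoints.items():
            for label, _, sd in rows:
                if sd < 0:
                    raise ValueError(f"negative SD for {ind} at {label}: {sd}")


def generate_eimd_panel(params: EIMDPanelParams) -> pd.DataFrame:
    """Tidy per-subject, per-timepoint indicator table.

    Each value is mean + SD * (sqrt(rho) z_subject + sqrt(1-rho) z), with
    the subject effect shared across an indicator's timepoints; soreness is
    clipped to the 0-10 scale and CK at zero.  Deterministic given the seed.
    """
    rng = np.random.default_rng(params.seed)
    rho = params.subject_rho
    rows = []
    for ind, tps in params.timepoints.items():
        z_subj = rng.normal(size=params.n_subjects)
        lo, hi = _INDICATOR_BOUNDS.get(ind, (None, None))
        for label, mean, sd in tps:
            z = rng.normal(size=params.n_subjects)
            vals = mean + sd * (math.sqrt(rho) * z_subj
                                + math.sqrt(1 - rho) * z)
            vals = np.clip(vals, lo, hi)
            for s, v in enumerate(vals):
                rows.append({"subject": s, "indicator": ind,
                             "timepoint": label, "value": float(v)})
    return pd.DataFrame(rows)
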