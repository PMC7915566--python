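import numpy as np
import pytest

from dvjmech.dynamics import DynamicsError, joint_power, newton_euler_planar
from dvjmech.kinematics import JointSeries
from dvjmech.model import GRAVITY, forward_kinematics


def _static_markers(subject, model, angles=None, n=50, toe_anchor=0.15):
    fk = forward_kinematics(np.zeros(4) if angles is None else angles,
                            subject, model, toe_anchor=toe_anchor)
    out = {}
    for key, lab in (("toe", "TOE"), ("heel", "HEEL"), ("ankle", "ANK"),
                     ("knee", "KNEE"), ("hip", "HIP")):
        out[f"R_{lab}"] = np.tile([fk[key][0], fk[key][1], 0.1], (n, 1))
    return out, fk


def _gravity_moments(fk, model, cop_x, leg_force):
    """Closed-form static internal moments from lever arms: for each joint
    the muscles must cancel the GRF moment (at the COP) plus the weights of
    the segments below the joint."""
    g = GRAVITY
    segs = model.segments
    loads = {
        "ankle": [("foot",)],
        "knee": [("foot",), ("shank",)],
        "hip": [("foot",), ("shank",), ("thigh",)],
    }
    coms = {"foot": fk["heel"] + segs["foot"]["com_fraction"]
            * (fk["toe"] - fk["heel"]),
            "shank": fk["knee"] + segs["shank"]["com_fraction"]
            * (fk["ankle"] - fk["knee"]),
            "thigh": fk["hip"] + segs["thigh"]["com_fraction"]
            * (fk["knee"] - fk["hip"])}
    out = {}
    for joint, below in loads.items():
        jp = fk[joint if joint != "ankle" else "ankle"]
        m_grf = (cop_x - jp[0]) * leg_force       # z-moment of GRF at COP
        m_w = sum(-(coms[s[0]][0] - jp[0]) * segs[s[0]]["mass"] * g
                  for s in below)
        out[joint] = -(m_grf + m_w)               # muscles cancel the load
    # clinical signs: plantarflexion = -z on the foot, extension = +z on
    # the shank, extension = -z on the thigh
    return {"ankle": -out["ankle"], "knee": out["knee"], "hip": -out["hip"]}


def test_static_squat_matches_lever_arm_closed_form(subject, model):
    angles = np.array([10.0, 50.0, 70.0, 25.0])
    markers, fk = _static_markers(subject, model, angles)
    leg_force = 0.5 * subject.mass * GRAVITY
    cop_x = fk["ankle"][0] + 0.05
    plate = np.tile([0.0, leg_force, cop_x], (50, 1))
    kin = newton_euler_planar(markers, plate, model, 200.0, check_cop=False)
    expected = _gravity_moments(fk, model, cop_x, leg_force)
    for joint in ("ankle", "knee", "hip"):
        mid = kin.moment[joint][10:-10]
        assert np.allclose(mid, expected[joint], rtol=5e-3), joint


def test_static_neutral_ankle_moment_from_cop_offset(subject, model):
    # COP 5 cm anterior to the ankle, half body weight on the leg:
    # plantarflexion moment = 0.5 * 773.9 N * 0.05 m = 19.35 Nm
    markers, fk = _static_markers(subject, model)
    leg_force = 0.5 * subject.mass * GRAVITY
    plate = np.tile([0.0, leg_force, fk["ankle"][0] + 0.05], (50, 1))
    kin = newton_euler_planar(markers, plate, model, 200.0, check_cop=False)
    mid = kin.moment["ankle"][10:-10]
    # small foot-weight correction enters the exact value; the COP lever
    # dominates
    expected = _gravity_moments(fk, model, fk["ankle"][0] + 0.05, leg_force)
    assert np.allclose(mid, expected["ankle"], rtol=5e-3)
    assert mid.mean() == pytest.approx(19.35, abs=1.2)
    assert kin.moment_norm["ankle"][25] == pytest.approx(
        kin.moment["ankle"][25] / subject.mass)


def test_zero_gravity_zero_motion_zero_grf_gives_zero_moments(subject, model):
    markers, _ = _static_markers(subject, model)
    plate = np.zeros((50, 3))
    kin = newton_euler_planar(markers, plate, model, 200.0, gravity=0.0,
                              check_cop=False)
    for joint in ("ankle", "knee", "hip"):
        assert np.abs(kin.moment[joint]).max() < 1e-9


def test_rotating_foot_matches_pendulum_closed_form(subject, model):
    # foot oscillating about a fixed ankle, leg static above, no GRF:
    # ankle moment (z) = I_com * alpha + m * a_com x r + gravity term,
    # equivalently the pivot form I_pivot * alpha + m g d sin(theta)
    n = 2000
    rate = 1000.0
    t = np.arange(n) / rate
    amp, f0 = np.deg2rad(12.0), 1.5
    phi = amp * np.sin(2 * np.pi * f0 * t)

    seg = model.segments["foot"]
    d_toe, d_heel = subject.length("toe"), subject.length("heel")
    h_a = subject.length("ankle_height")
    fk = forward_kinematics(np.zeros(4), subject, model, toe_anchor=0.15)
    ankle = fk["ankle"]
    toe0 = fk["toe"] - ankle
    heel0 = fk["heel"] - ankle

    def rot(p, a):
        c, s = np.cos(a), np.sin(a)
        return np.column_stack([c * p[0] - s * p[1], s * p[0] + c * p[1]])

    markers = {
        "R_ANK": np.column_stack([np.full(n, ankle[0]), np.full(n, ankle[1]),
                                  np.full(n, 0.1)]),
        "R_TOE": np.column_stack([ankle + rot(toe0, phi),
                                  np.full(n, 0.1)]),
        "R_HEEL": np.column_stack([ankle + rot(heel0, phi),
                                   np.full(n, 0.1)]),
        "R_KNEE": np.tile([fk["knee"][0], fk["knee"][1], 0.1], (n, 1)),
        "R_HIP": np.tile([fk["hip"][0], fk["hip"][1], 0.1], (n, 1)),
    }
    plate = np.zeros((n, 3))
    kin = newton_euler_planar(markers, plate, model, rate, check_cop=False)

    com0 = fk["heel"] + seg["com_fraction"] * (fk["toe"] - fk["heel"]) - ankle
    d = np.hypot(*com0)
    theta0 = np.arctan2(com0[0], -com0[1])     # from straight down
    alpha = -amp * (2 * np.pi * f0) ** 2 * np.sin(2 * np.pi * f0 * t)
    i_pivot = seg["inertia"] + seg["mass"] * d**2
    m_pivot_z = i_pivot * alpha + seg["mass"] * GRAVITY * d * np.sin(
        theta0 + phi)
    expected = -m_pivot_z                      # plantarflexion positive
    mid = slice(50, -50)
    scale = np.abs(expected[mid]).max()
    assert np.abs(kin.moment["ankle"][mid] - expected[mid]).max() < 0.01 * scale


def test_moments_linear_in_grf(subject, model, baseline_clean):
    from dvjmech.signal import butterworth_lowpass, downsample_force_to_kin
    markers = {lab: butterworth_lowpass(arr, 200.0, axis=0)
               for lab, arr in baseline_clean.markers.items()}
    plate = downsample_force_to_kin(baseline_clean.plates["R"], 1000.0,
                                    200.0, axis=0)
    k1 = newton_euler_planar(markers, plate, model, 200.0, check_cop=False)
    plate2 = plate.copy()
    plate2[:, :2] *= 2.0
    k2 = newton_euler_planar(markers, plate2, model, 200.0, check_cop=False)
    k0 = newton_euler_planar(markers, plate * [0.0, 0.0, 1.0], model, 200.0,
                             check_cop=False)
    for joint in ("ankle", "knee", "hip"):
        lhs = k2.moment[joint] - k0.moment[joint]
        rhs = 2 * (k1.moment[joint] - k0.moment[joint])
        np.testing.assert_allclose(lhs, rhs, atol=1e-6)


def test_power_definition_and_signs(subject, model):
    from dvjmech.dynamics import KineticsSeries
    ks = KineticsSeries(rate=200.0, mass=subject.mass)
    ks.moment = {"knee": np.full(10, 2.0 * subject.mass)}   # 2 Nm/kg raw
    ks.moment_norm = {"knee": np.full(10, 2.0)}
    js = JointSeries(rate=200.0)
    js.velocity = {"knee": np.full(10, -np.rad2deg(1.0))}   # extending
    out = joint_power(ks, js)
    np.testing.assert_allclose(out.power_norm["knee"], 2.0, atol=1e-12)
    js.velocity["knee"][:] = 0.0
    out = joint_power(ks, js)
    np.testing.assert_allclose(out.power_norm["knee"], 0.0, atol=1e-12)


def test_power_length_mismatch_rejected(subject):
    from dvjmech.dynamics import KineticsSeries
    ks = KineticsSeries(rate=200.0, mass=subject.mass)
    ks.moment = {"knee": np.zeros(10)}
    ks.moment_norm = {"knee": np.zeros(10)}
    js = JointSeries(rate=200.0)
    js.velocity = {"knee": np.zeros(8)}
    with pytest.raises(DynamicsError, match="mismatch"):
        joint_power(ks, js)


def test_landing_sign_pattern(damaged_analysis):
    """During landing the knee extensors resist flexion: positive internal
    extension moment, negative (absorbing) knee power; propulsion shows
    positive (generating) knee power."""
    m = damaged_analysis.metrics
    assert m.peak_knee_moment_landing > 0
    assert m.peak_knee_power_absorption_landing < 0
    assert m.peak_knee_power_generation_propulsion > 0
    assert m.knee_stiffness > 0
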