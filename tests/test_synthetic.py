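import numpy as np
import pytest

from dvjmech import synthetic as syn
from dvjmech.kinematics import (ankle_neutral_offset, joint_angles,
                                pelvis_height)
from dvjmech.model import GRAVITY


class TestPresets:
    def test_table_values(self):
        b = syn.preset("baseline")
        assert b.peak_knee_flexion == 84.15
        assert b.knee_flexion_ic == 41.61
        assert b.jump_height == 33.38
        d = syn.preset("damaged48h")
        assert d.landing_duration == 173.3
        assert d.landing_duration + d.propulsion_duration == pytest.approx(381.7)
        assert d.peak_hip_flexion > b.peak_hip_flexion

    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(KeyError, match="baseline"):
            syn.preset("recovered96h")

    @pytest.mark.parametrize("bad", [
        dict(drop_height=0.0),
        dict(landing_duration=-5.0),
        dict(marker_noise_sd=-1e-4),
        dict(knee_flexion_ic=50.0, peak_knee_flexion=40.0),
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(syn.InfeasibleTrialError):
            syn.ConditionParams(**bad)

    def test_dynamically_impossible_duration_rejected(self, subject):
        # landing far slower than the CoM can float
        params = syn.preset("baseline", landing_duration=600.0)
        with pytest.raises(syn.InfeasibleTrialError):
            syn.plan_dvj_trial(subject, params)


class TestGeneratedTrial:
    def test_raw_peak_knee_matches_prescription(self, baseline_clean,
                                                static_clean):
        # unfiltered marker route: the generated knee trajectory peaks at
        # exactly the prescribed angle
        plan = baseline_clean.meta["plan"]
        off = ankle_neutral_offset(static_clean)
        js = joint_angles(baseline_clean.markers, 200.0, off)
        t = baseline_clean.time_kin()
        contact = (t >= plan.t_ic) & (t < plan.t_takeoff)
        assert js.angle["knee"][contact].max() == pytest.approx(84.15,
                                                                abs=0.01)

    def test_raw_prescription_fidelity_all_joints(self, damaged_clean,
                                                  static_clean):
        plan = damaged_clean.meta["plan"]
        p = damaged_clean.meta["params"]
        off = ankle_neutral_offset(static_clean)
        js = joint_angles(damaged_clean.markers, 200.0, off)
        i_ic = int(round(plan.t_ic * 200))
        for joint, ic, pk in (("pelvis", p.pelvic_tilt_ic, p.peak_pelvic_tilt),
                              ("hip", p.hip_flexion_ic, p.peak_hip_flexion),
                              ("knee", p.knee_flexion_ic, p.peak_knee_flexion),
                              ("ankle", p.ankle_ic, p.peak_ankle)):
            assert js.angle[joint][i_ic] == pytest.approx(ic, abs=0.1)
            t = damaged_clean.time_kin()
            landing = (t >= plan.t_ic) & (t <= plan.t_peak + 1e-9)
            assert js.angle[joint][landing].max() == pytest.approx(pk, abs=0.1)

    def test_flight_grf_is_zero(self, baseline_clean):
        plan = baseline_clean.meta["plan"]
        t = baseline_clean.time_force()
        fy = baseline_clean.total_vertical_grf()
        flight = (t < plan.t_ic) | (t >= plan.t_takeoff)
        assert np.abs(fy[flight]).max() == 0.0

    @pytest.mark.parametrize("fixture", ["baseline_clean", "damaged_clean"])
    def test_impulse_momentum_closure(self, fixture, request):
        trial = request.getfixturevalue(fixture)
        plan = trial.meta["plan"]
        m = trial.subject.mass
        t = trial.time_force()
        fy = trial.total_vertical_grf()
        contact = (t >= plan.t_ic) & (t < plan.t_takeoff)
        impulse = np.trapezoid(fy[contact] - m * GRAVITY, dx=1e-3)
        dv = m * (plan.com_vel_takeoff[1] - plan.com_vel_ic[1])
        assert impulse == pytest.approx(dv, rel=0.01)

    def test_flight_apex_matches_jump_height(self, baseline_clean,
                                             static_clean):
        plan = baseline_clean.meta["plan"]
        t = baseline_clean.time_kin()
        ph = pelvis_height(baseline_clean.markers)
        ref = pelvis_height(static_clean.markers).mean()
        apex_cm = (ph[t >= plan.t_takeoff].max() - ref) * 100
        assert apex_cm == pytest.approx(33.38, abs=0.2)

    def test_identical_seed_is_bitwise_identical(self, subject, model):
        p = syn.preset("baseline", seed=77)
        a = syn.generate_dvj_trial(subject, p, model)
        b = syn.generate_dvj_trial(subject, p, model)
        for lab in a.markers:
            np.testing.assert_array_equal(a.markers[lab], b.markers[lab])
        for pid in a.plates:
            np.testing.assert_array_equal(a.plates[pid], b.plates[pid])

    def test_marker_continuity_across_phases(self, baseline_clean):
        # no jumps anywhere in the marker streams (velocity bounded)
        for lab, arr in baseline_clean.markers.items():
            step = np.abs(np.diff(arr[:, :2], axis=0)).max()
            assert step < 0.10, lab   # < 20 m/s at 200 Hz


class TestStaticTrial:
    def test_total_grf_equals_body_weight(self, static_clean, subject):
        mean_fy = static_clean.total_vertical_grf().mean()
        assert mean_fy == pytest.approx(subject.mass * GRAVITY, abs=0.5)
        assert mean_fy == pytest.approx(773.9, abs=0.5)

    def test_pelvis_height_constant(self, static_clean):
        ph = pelvis_height(static_clean.markers)
        assert ph.max() - ph.min() == pytest.approx(0.0, abs=1e-12)

    def test_neutral_knee_angle_zero(self, static_clean):
        off = ankle_neutral_offset(static_clean)
        js = joint_angles(static_clean.markers, 200.0, off)
        assert np.abs(js.angle["knee"]).max() < 0.1


class TestCohortSampling:
    def test_feasible_pairs_generate_and_differ(self, rng, subject, model):
        a, b = syn.sample_feasible_paired_conditions(rng, subject, model)
        assert b.peak_knee_flexion != a.peak_knee_flexion
        syn.generate_dvj_trial(subject, a, model)
        syn.generate_dvj_trial(subject, b, model)

    def test_sampled_peaks_respect_ordering(self, rng, subject, model):
        for i in range(10):
            a, b = syn.sample_feasible_paired_conditions(rng, subject, model)
            for cp in (a, b):
                assert cp.peak_knee_flexion >= cp.knee_flexion_ic
                assert cp.peak_hip_flexion >= cp.hip_flexion_ic
                assert cp.peak_pelvic_tilt >= cp.pelvic_tilt_ic


class TestEIMDPanel:
    def test_zero_sd_reproduces_means_exactly(self):
        tps = {"IPT_pct": [("0h", 100.0, 0.0), ("48h", 80.5, 0.0)]}
        panel = syn.generate_eimd_panel(
            syn.EIMDPanelParams(timepoints=tps, n_subjects=5, seed=1))
        at48 = panel[(panel.indicator == "IPT_pct")
                     & (panel.timepoint == "48h")].value
        assert (at48 == 80.5).all()

    def test_same_seed_identical(self):
        a = syn.generate_eimd_panel(syn.EIMDPanelParams(seed=9))
        b = syn.generate_eimd_panel(syn.EIMDPanelParams(seed=9))
        assert a.equals(b)

    def test_soreness_clipped_to_scale(self):
        tps = {"DOMS": [("48h", 9.5, 4.0)]}
        panel = syn.generate_eimd_panel(
            syn.EIMDPanelParams(timepoints=tps, n_subjects=200, seed=3))
        assert panel.value.between(0, 10).all()
        assert (panel.value == 10).any()   # clipping actually engaged

    def test_negative_sd_rejected(self):
        tps = {"CK": [("0h", 202.0, -1.0)]}
        with pytest.raises(ValueError, match="negative SD"):
            syn.EIMDPanelParams(timepoints=tps)

    def test_grand_mean_recovers_configured_mean(self):
        # 300 replicate panels: SE of the grand mean ~ 0.16 %-points
        vals = []
        for s in range(300):
            panel = syn.generate_eimd_panel(syn.EIMDPanelParams(seed=s))
            sub = panel[(panel.indicator == "IPT_pct")
                        & (panel.timepoint == "48h")]
            vals.append(sub.value.mean())
        assert np.mean(vals) == pytest.approx(80.5, abs=1.0)
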