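"""Joint angles, planar arch angles, ROM and marker-set comparisons."""

import numpy as np
import pytest

import afmkin as ak
from afmkin.angles import mla_from_points, trial_angles
from afmkin.errors import AfmError
from afmkin.geometry import Frame, compose_cardan_zxy, rot_axis
from afmkin.model import MarkerSet
from conftest import random_rotation

PLANES = ("sagittal", "frontal", "transverse")


class TestJointAngle:
    def test_identical_frames_zero(self):
        f = Frame(np.zeros(3), compose_cardan_zxy(12.0, 3.0, -8.0))
        assert ak.joint_angles_at({"shank": f, "hindfoot": f})["HF_SK"] == \
            pytest.approx((0, 0, 0), abs=1e-10)

    def test_plantarflexion_sign(self):
        """-20 deg about the proximal z axis is plantar flexion."""
        prox = Frame(np.zeros(3), np.eye(3))
        dist = Frame(np.zeros(3), rot_axis("z", -20.0))
        a = ak.joint_angles_at({"shank": prox, "hindfoot": dist})["HF_SK"]
        assert a.sagittal == pytest.approx(-20.0, abs=1e-10)
        assert a.frontal == pytest.approx(0.0, abs=1e-10)
        assert a.transverse == pytest.approx(0.0, abs=1e-10)

    def test_hallux_frontal_absent(self):
        f = Frame(np.zeros(3), np.eye(3))
        a = ak.joint_angles_at({"medial_forefoot": f, "hallux": f})["HX_FFM"]
        assert np.isnan(a.frontal)

    def test_foot_shank_hook(self):
        """F_SK is computed only when an external foot frame is supplied."""
        f = Frame(np.zeros(3), np.eye(3))
        foot = Frame(np.zeros(3), rot_axis("z", 5.0))
        out = ak.joint_angles_at({"shank": f, "foot": foot}, joints=("F_SK",))
        assert out["F_SK"].sagittal == pytest.approx(5.0, abs=1e-10)
        assert ak.joint_angles_at({"shank": f}, joints=("F_SK",)) == {}


class TestRecovery:
    def test_noise_free_recovery_all_joints(self, gait_clean, cal, clean_curves):
        """The full pipeline recovers every prescribed curve to numerical
        precision on noise-free rigid-segment gait."""
        for key, truth in gait_clean.truth.items():
            if key not in clean_curves:
                continue
            err = np.nanmax(np.abs(clean_curves[key].values - truth))
            assert err < 1e-6, key

    def test_noisy_recovery_rms(self, gait_noisy, cal):
        """0.5 mm isotropic marker noise keeps the RMS curve error small."""
        curves = trial_angles(gait_noisy.trial, cal)
        for key, truth in gait_noisy.truth.items():
            if key not in curves:
                continue
            rms = np.sqrt(np.nanmean((curves[key].values - truth) ** 2))
            assert rms < 3.0, key

    def test_left_right_symmetry(self, cal, clean_curves):
        """The mirrored left foot yields identical curves in all planes."""
        gl = ak.synthesize_gait(side="left")
        call = ak.calibrate_static(ak.make_static_trial(ak.template_foot("left")),
                                   side="left")
        cl = trial_angles(gl.clean_trial, call)
        for key in clean_curves:
            d = np.abs(cl[key].values - clean_curves[key].values)
            assert np.nanmax(d) < 1e-9, key

    def test_rigid_motion_invariance(self, gait_clean, cal, clean_curves):
        """All angle outputs (joints, MLA, TTA) are invariant under a global
        rigid motion of the dynamic trial."""
        rng = np.random.default_rng(13)
        R = random_rotation(rng)
        t = rng.normal(scale=500, size=3)
        trial = gait_clean.clean_trial
        moved = ak.Trial(trial.labels, trial.data @ R.T + t, trial.rate)
        curves2 = trial_angles(moved, cal)
        for key in clean_curves:
            d = np.abs(curves2[key].values - clean_curves[key].values)
            assert np.nanmax(d) < 1e-9, key


class TestMla:
    def test_planar_trigonometry_oracle(self):
        """CAp=(0,0,0), NAV=(60,40,0), HM1p=(120,0,0): the arch angle is
        2*atan(60/40)."""
        out = mla_from_points(np.array([60.0, 40.0, 0.0]), np.zeros(3),
                              np.array([120.0, 0.0, 0.0]))
        assert out == pytest.approx(np.degrees(2 * np.arctan(60 / 40)), abs=1e-9)

    def test_whole_foot_rigid_motion_invariance(self, gait_clean, cal):
        trial = gait_clean.clean_trial
        recon = ak.reconstruct_frames(trial, cal)
        hf, ff = recon.frames["hindfoot"][0], recon.frames["forefoot"][0]
        nav = trial.positions("NAV")[0]
        base = ak.mla(hf, ff, nav, cal)
        rng = np.random.default_rng(2)
        R = random_rotation(rng)
        t = rng.normal(scale=100, size=3)
        hf2 = Frame(R @ hf.origin + t, R @ hf.rotation)
        ff2 = Frame(R @ ff.origin + t, R @ ff.rotation)
        assert ak.mla(hf2, ff2, R @ nav + t, cal) == pytest.approx(base, abs=1e-9)

    def test_raising_navicular_lowers_angle(self):
        """A higher arch gives a smaller MLA (larger angle = flatter foot)."""
        cap = np.zeros(3)
        hm1p = np.array([120.0, 0.0, 0.0])
        heights = np.linspace(20, 80, 7)
        angles = [mla_from_points(np.array([60.0, h, 0.0]), cap, hm1p) for h in heights]
        assert np.all(np.diff(angles) < 0)

    def test_missing_calibration_points_rejected(self, template, cal):
        import dataclasses
        broken = dataclasses.replace(cal, cap_in_hindfoot=None)
        f = Frame(np.zeros(3), np.eye(3))
        with pytest.raises(AfmError, match="CAp"):
            ak.mla(f, f, np.zeros(3), broken)


class TestTta:
    def test_collinear_is_flat(self):
        ms = MarkerSet({"BM1": (0, 0, 0), "BM2": (1, 0, 0), "BM5": (2, 0, 0)})
        assert ak.tta(ms) == pytest.approx(0.0, abs=1e-9)

    def test_right_angle_oracle(self):
        ms = MarkerSet({"BM1": (0, 0, 0), "BM2": (1, 1, 0), "BM5": (2, 0, 0)})
        assert ak.tta(ms) == pytest.approx(90.0, abs=1e-9)

    def test_rigid_invariance(self, template):
        rng = np.random.default_rng(17)
        R = random_rotation(rng)
        moved = template.transformed(R, rng.normal(size=3))
        assert ak.tta(moved) == pytest.approx(ak.tta(template), abs=1e-9)


class TestRom:
    def test_constant_curve(self):
        assert ak.rom([4.0, 4.0, 4.0]) == 0.0

    def test_simple_arithmetic(self):
        assert ak.rom([-5.0, 10.0, 3.0]) == 15.0

    def test_multi_trial_mean(self):
        assert ak.rom([[0.0, 2.0], [0.0, 4.0]]) == pytest.approx(3.0)

    def test_all_gap_rejected(self):
        with pytest.raises(AfmError):
            ak.rom([np.nan, np.nan])

    def test_prescribed_amplitude_recovered(self, gait_clean, cal, clean_curves):
        """A sinusoidal prescription of amplitude a appears as ROM = 2a after
        the full pipeline and stride normalization."""
        ev = ak.detect_events(gait_clean.clean_trial)
        mean, strides = ak.normalize_stride(clean_curves[("HF_SK", "sagittal")], ev)
        amp = gait_clean.profile.hf_sk["sagittal"].amplitude
        assert ak.rom(strides) == pytest.approx(2 * amp, abs=0.1)


class TestTwoMarkerSets:
    def test_identical_sets_zero(self, template_v):
        out = ak.angles_from_two_marker_sets(template_v, template_v)
        for err in out.segment_errors.values():
            assert np.max(np.abs(err)) < 1e-10
        for diff in out.joint_differences.values():
            assert np.nanmax(np.abs(diff)) < 1e-10

    def test_rigid_motion_of_b_zero_difference(self, template_v):
        rng = np.random.default_rng(23)
        moved = template_v.transformed(random_rotation(rng), rng.normal(size=3))
        out = ak.angles_from_two_marker_sets(template_v, moved)
        for err in out.segment_errors.values():
            assert np.max(np.abs(err)) < 1e-8

    def test_calp_displacement_matches_sensitivity_gradient(self, template):
        """Displacing CALP 2 mm medially reproduces twice the per-mm
        frontal-plane sensitivity gradient of the hindfoot."""
        disp = ak.displacement_frame(template)
        medial = -disp.z  # medial = minus the medio-lateral axis (right foot)
        moved = template.replace("CALP", template["CALP"] + 2.0 * medial)
        # no global motion between the sets, so skip the rigid registration
        out = ak.angles_from_two_marker_sets(template, moved, align=False,
                                             segments=("hindfoot",), joints=())
        grad = [r for r in ak.marker_sensitivity(template, "hindfoot", "CALP")
                if r.axis == "medio_lateral" and r.plane == "frontal"][0]
        assert abs(out.segment_errors["hindfoot"].frontal) == \
            pytest.approx(2.0 * grad.gradient, rel=0.02)
        # and both agree with the small-angle closed form to ~10%
        closed = 2.0 * np.degrees(1.0 / 40.0)
        assert abs(out.segment_errors["hindfoot"].frontal) == pytest.approx(closed, rel=0.1)
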