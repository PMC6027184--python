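"""Kinematic decomposition, comparison metrics and EMG processing."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

import elbowsim as es
from elbowsim.errors import ShapeError, UndefinedCorrelationError
from elbowsim.evaluation import compose_relative_pose
from elbowsim.kinematics import MotionTrial, PoseSeries, quat_from_axis_angle

IDENTITY_FRAMES = {
    name: es.AnatomicalFrame(origin=np.zeros(3), axes=np.eye(3))
    for name in ("humerus", "ulna", "radius")}


def _trial_from_relative(positions, quats, body="ulna"):
    """Humerus fixed at identity; one child posed per frame; the other child
    rides along at identity."""
    n = len(positions)
    ident_p = np.zeros((n, 3))
    ident_q = np.tile([1.0, 0, 0, 0], (n, 1))
    bodies = {"humerus": PoseSeries(ident_p.copy(), ident_q.copy()),
              "ulna": PoseSeries(ident_p.copy(), ident_q.copy()),
              "radius": PoseSeries(ident_p.copy(), ident_q.copy())}
    bodies[body] = PoseSeries(np.asarray(positions, float),
                              np.asarray(quats, float))
    return MotionTrial(label="t", time=np.arange(n) * 0.01, bodies=bodies)


class TestDecomposition:
    def test_identity_pose_gives_zero_channels(self):
        trial = _trial_from_relative(np.zeros((3, 3)),
                                     np.tile([1.0, 0, 0, 0], (3, 1)))
        ks = es.decompose_kinematics(trial, IDENTITY_FRAMES)
        assert np.allclose(ks.data.to_numpy(), 0.0, atol=1e-9)
        assert list(ks.data.columns) == es.CHANNELS

    def test_pure_flexion_maps_to_the_fe_channel(self):
        q = quat_from_axis_angle([1, 0, 0], np.deg2rad(30.0))
        trial = _trial_from_relative(np.zeros((2, 3)), np.tile(q, (2, 1)))
        ks = es.decompose_kinematics(trial, IDENTITY_FRAMES)
        assert np.allclose(ks.channel("ulna_FE_deg"), 30.0, atol=1e-9)
        assert np.allclose(ks.channel("ulna_VV_deg"), 0.0, atol=1e-9)
        assert np.allclose(ks.channel("ulna_IE_deg"), 0.0, atol=1e-9)

    def test_pure_medial_translation_maps_to_ml(self):
        pos = np.tile([5.0, 0.0, 0.0], (2, 1))
        trial = _trial_from_relative(pos, np.tile([1.0, 0, 0, 0], (2, 1)))
        ks = es.decompose_kinematics(trial, IDENTITY_FRAMES)
        assert np.allclose(ks.channel("ulna_ML_mm"), 5.0, atol=1e-12)
        assert np.allclose(ks.channel("ulna_AP_mm"), 0.0, atol=1e-12)
        assert np.allclose(ks.channel("ulna_SI_mm"), 0.0, atol=1e-12)

    def test_round_trip_recomposition(self, rng):
        for _ in range(20):
            fe, vv, ie = rng.uniform([-150, -40, -80], [150, 40, 80])
            trans = rng.uniform(-20, 20, 3)
            r = Rotation.from_euler("XYZ", [fe, vv, ie], degrees=True)
            q = np.roll(r.as_quat(), 1)  # scalar-first
            trial = _trial_from_relative(trans[None, :].repeat(2, 0),
                                         np.tile(q, (2, 1)))
            ks = es.decompose_kinematics(trial, IDENTITY_FRAMES)
            got = [ks.channel(f"ulna_{c}_deg")[0] for c in ("FE", "VV", "IE")]
            r_back, t_back = compose_relative_pose(
                *got, *[ks.channel(f"ulna_{c}_mm")[0] for c in ("ML", "AP", "SI")])
            assert np.allclose(r_back, r.as_matrix(), atol=1e-9)
            assert np.allclose(t_back, trans, atol=1e-9)

    def test_gimbal_proximity_warns(self):
        q = quat_from_axis_angle([0, 1, 0], np.deg2rad(89.5))
        trial = _trial_from_relative(np.zeros((2, 3)), np.tile(q, (2, 1)))
        with pytest.warns(UserWarning, match="gimbal"):
            es.decompose_kinematics(trial, IDENTITY_FRAMES)

    def test_missing_frame_raises(self):
        trial = _trial_from_relative(np.zeros((2, 3)),
                                     np.tile([1.0, 0, 0, 0], (2, 1)))
        with pytest.raises(ShapeError):
            es.decompose_kinematics(trial, {"humerus": IDENTITY_FRAMES["humerus"]})


class TestScalarMetrics:
    def test_rms_trivials(self):
        a = np.array([1.0, 2.0, 3.0])
        assert es.rms_error(a, a) == 0.0
        assert es.rms_error(a, a + 2.0) == pytest.approx(2.0)

    def test_rms_matches_brute_force_loop(self, rng):
        a = rng.normal(size=500)
        b = rng.normal(size=500)
        acc = 0.0
        for x, y in zip(a, b):
            acc += (x - y) ** 2
        assert es.rms_error(a, b) == pytest.approx(np.sqrt(acc / 500),
                                                   abs=1e-12)

    def test_rms_length_mismatch(self):
        with pytest.raises(ShapeError):
            es.rms_error(np.ones(3), np.ones(4))

    def test_pearson_trivials(self):
        a = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        assert es.pearson_r(a, a) == pytest.approx(1.0)
        assert es.pearson_r(a, -a) == pytest.approx(-1.0)

    def test_pearson_matches_textbook_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        am, bm = a - a.mean(), b - b.mean()
        expected = (am @ bm) / np.sqrt((am @ am) * (bm @ bm))
        assert es.pearson_r(a, b) == pytest.approx(expected, abs=1e-12)

    def test_pearson_matches_loop_computation(self, rng):
        a, b = rng.normal(size=300), rng.normal(size=300)
        n = len(a)
        sa, sb = sum(a), sum(b)
        sab = sum(x * y for x, y in zip(a, b))
        saa = sum(x * x for x in a)
        sbb = sum(y * y for y in b)
        expected = ((n * sab - sa * sb)
                    / np.sqrt((n * saa - sa ** 2) * (n * sbb - sb ** 2)))
        assert es.pearson_r(a, b) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_is_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            es.pearson_r(np.ones(5), np.arange(5.0))


class TestEMG:
    def test_constant_signal_processes_to_zero(self):
        raw = pd.DataFrame({"biceps": np.full(1400, 0.37)})
        with pytest.warns(UserWarning, match="identically zero"):
            env = es.process_emg(raw, rate=1400.0)
        assert np.allclose(env.data["biceps"], 0.0)

    def test_trial_max_normalization_is_exact(self, rng):
        raw = pd.DataFrame({"ch": rng.normal(size=7000)})
        env = es.process_emg(raw, rate=1400.0)
        assert env.data["ch"].max() == pytest.approx(1.0, abs=1e-12)

    def test_50hz_carrier_ripple_attenuated_per_filter_gain(self):
        rate, f_carrier = 1400.0, 50.0
        t = np.arange(int(10 * rate)) / rate
        raw = pd.DataFrame({"ch": np.sin(2 * np.pi * f_carrier * t)})
        env = es.process_emg(raw, rate=rate)
        y = env.data["ch"].to_numpy()[int(2 * rate):]  # past the transient
        ripple = 0.5 * (y.max() - y.min())
        mean = y.mean()
        # rectified sine = DC (2A/pi) + 100 Hz harmonic (4A/3pi); the
        # second-order Butterworth leaves |H| = 1/sqrt(1+(f/fc)^4) of it
        h100 = 1.0 / np.sqrt(1.0 + (2 * f_carrier / 6.0) ** 4)
        assert ripple / mean == pytest.approx((2.0 / 3.0) * h100, rel=0.5)
        assert ripple / mean < 0.01

    def test_low_rate_rejected(self):
        with pytest.raises(es.errors.ParameterError):
            es.process_emg(pd.DataFrame({"ch": np.ones(10)}), rate=10.0)

    def test_zero_phase_flag(self, rng):
        raw = pd.DataFrame({"ch": rng.normal(size=7000)})
        causal = es.process_emg(raw, rate=1400.0)
        zero = es.process_emg(raw, rate=1400.0, zero_phase=True)
        assert not np.allclose(causal.data["ch"], zero.data["ch"])


class TestForceNormalization:
    def test_max_one_and_scale_invariance(self, rng):
        f = pd.DataFrame({"m": np.abs(rng.normal(size=100))})
        n1 = es.normalize_muscle_forces(f)
        n2 = es.normalize_muscle_forces(2.0 * f)
        assert n1["m"].max() == 1.0
        assert np.allclose(n1["m"], n2["m"])

    def test_zero_muscle_warns_and_returns_zeros(self):
        with pytest.warns(UserWarning, match="no force"):
            out = es.normalize_muscle_forces(pd.DataFrame({"m": np.zeros(10)}))
        assert np.all(out["m"] == 0.0)

    def test_onset_times_preserved(self, rng):
        x = np.concatenate([np.zeros(40), np.linspace(0, 3.0, 60)])
        norm = es.normalize_muscle_forces(pd.DataFrame({"m": x}))["m"].to_numpy()
        onset_raw = np.argmax(x > 0.1 * x.max())
        onset_norm = np.argmax(norm > 0.1)
        assert onset_raw == onset_norm


class TestReport:
    def _series(self, data, time=None):
        time = np.arange(len(data)) * 0.01 if time is None else time
        return es.KinematicsSeries(time=time, data=data)

    def _random_series(self, rng, n=200):
        return self._series(pd.DataFrame(
            {c: rng.normal(size=n).cumsum() for c in es.CHANNELS}))

    def test_self_comparison_is_perfect(self, rng):
        ref = self._random_series(rng)
        rep = es.build_report(ref, ref)
        assert len(rep) == 12
        assert np.allclose(rep["rms_error"], 0.0)
        assert np.allclose(rep["correlation"], 1.0)
        assert rep["good"].all()

    def test_constant_offset_changes_rms_not_correlation(self, rng):
        ref = self._random_series(rng)
        shifted = ref.data.copy()
        shifted["ulna_FE_deg"] += 2.0
        rep = es.build_report(ref, self._series(shifted)).set_index("channel")
        assert rep.loc["ulna_FE_deg", "rms_error"] == pytest.approx(2.0)
        assert rep.loc["ulna_FE_deg", "correlation"] == pytest.approx(1.0)

    def test_row_order_matches_the_standard_table(self, rng):
        rep = es.build_report(self._random_series(rng),
                              self._random_series(rng))
        assert list(rep["channel"]) == es.CHANNELS

    def test_shuffled_series_decorrelate(self, rng):
        ref = self._random_series(rng, n=400)
        rs = []
        for seed in range(10):
            perm = np.random.default_rng(seed).permutation(400)
            shuffled = ref.data.iloc[perm].reset_index(drop=True)
            rep = es.build_report(ref, self._series(shuffled))
            rs.append(rep["correlation"].abs().mean())
        assert np.mean(rs) < 0.2
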