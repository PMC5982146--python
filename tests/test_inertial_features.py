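import numpy as np
import pytest

from gaitkit import (
    build_stride_cycles,
    detect_heel_strikes_accel,
    extract_inertial_stride,
    harmonize_axes,
    normalize_by_height,
    residual_magnitude,
    tilt_angles,
)
from gaitkit.exceptions import FeatureError, ParameterError
from gaitkit.gait_events import StrideCycle
from gaitkit.inertial_features import extract_inertial_trial
from gaitkit.signal_io import AccelTrace, SubjectMeta

from conftest import truth_strides


def _anat(lat, vert, ant, fs=200.0):
    n = len(vert)
    return AccelTrace(
        t=np.arange(n) / fs,
        ax=np.asarray(vert, float),
        ay=np.asarray(ant, float),
        az=np.asarray(lat, float),
        fs=fs,
        side="left",
        frame="anatomical",
    )


def _cycle(hs_idx, next_idx, fs=200.0, stance_frac=0.6):
    return StrideCycle(
        side="left",
        hs_time=hs_idx / fs,
        next_hs_time=next_idx / fs,
        stance_end_time=(hs_idx + stance_frac * (next_idx - hs_idx)) / fs,
        hs_index=hs_idx,
        next_hs_index=next_idx,
    )


class TestResidualMagnitude:
    def test_stationary_gravity_cancels(self):
        assert np.all(residual_magnitude(np.zeros(5), np.ones(5), np.zeros(5)) == 0)

    def test_double_gravity_gives_one(self):
        assert residual_magnitude(np.zeros(3), 2 * np.ones(3), np.zeros(3)) == pytest.approx(
            np.ones(3)
        )

    def test_matches_per_sample_brute_force(self):
        rng = np.random.default_rng(1)
        lat, vert, ant = rng.normal(size=(3, 50))
        fast = residual_magnitude(lat, vert, ant)
        slow = np.array(
            [abs(np.sqrt(l * l + v * v + a * a) - 1.0) for l, v, a in zip(lat, vert, ant)]
        )
        assert np.array_equal(fast, slow)


class TestTiltAngles:
    def test_static_upright_is_zero(self):
        lat, ant = tilt_angles(np.zeros(100), np.ones(100), np.zeros(100), fs=200.0)
        assert np.allclose(lat, 0.0, atol=1e-9)
        assert np.allclose(ant, 0.0, atol=1e-9)

    def test_static_ten_degree_anterior_tilt(self):
        th = np.radians(10.0)
        n = 100
        lat, ant = tilt_angles(
            np.zeros(n), np.full(n, np.cos(th)), np.full(n, np.sin(th)), fs=200.0
        )
        assert np.allclose(ant, 10.0, atol=1e-6)

    def test_slow_rocking_sd_recovered(self):
        # +/-5 deg lateral rocking at 0.5 Hz over 10 s
        fs = 200.0
        t = np.arange(int(10 * fs)) / fs
        theta = np.radians(5.0) * np.sin(2 * np.pi * 0.5 * t)
        lat, _ = tilt_angles(np.sin(theta), np.cos(theta), np.zeros_like(t), fs=fs)
        mid = slice(400, 1600)  # avoid filter edge effects
        sd_true = float(np.std(np.degrees(theta[mid])))
        sd_est = float(np.std(lat[mid]))
        assert abs(sd_est - sd_true) / sd_true < 0.10

    def test_free_fall_rejected(self):
        with pytest.raises(FeatureError):
            tilt_angles(np.zeros(100), np.zeros(100), np.zeros(100), fs=200.0)


class TestExtractInertial:
    def test_stride_time_from_indices(self):
        trace = _anat(np.zeros(3000), np.ones(3000), np.zeros(3000))
        feats = extract_inertial_stride(_cycle(2000, 2240), trace)
        assert feats.st == pytest.approx(1.2)

    def test_constant_initial_window_gives_zero_impulse(self):
        trace = _anat(0.3 * np.ones(1000), np.ones(1000), 0.1 * np.ones(1000))
        feats = extract_inertial_stride(_cycle(100, 340), trace)
        for v in (feats.imp_l, feats.imp_v, feats.imp_a):
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_vm10_equals_vm_for_constant_residual(self):
        trace = _anat(np.zeros(1000), 2.0 * np.ones(1000), np.zeros(1000))
        feats = extract_inertial_stride(_cycle(100, 340), trace)
        assert feats.vm == pytest.approx(1.0)
        assert feats.vm10 == pytest.approx(feats.vm)

    def test_mag_invariant_to_axis_sign(self):
        rng = np.random.default_rng(2)
        lat = rng.normal(0, 0.3, 1000)
        trace = _anat(lat, np.ones(1000), np.zeros(1000))
        flipped = _anat(-lat, np.ones(1000), np.zeros(1000))
        a = extract_inertial_stride(_cycle(100, 340), trace)
        b = extract_inertial_stride(_cycle(100, 340), flipped)
        assert a.mag_l == pytest.approx(b.mag_l)

    def test_short_initial_window_is_feature_error(self):
        trace = _anat(np.zeros(100), np.ones(100), np.zeros(100))
        with pytest.raises(FeatureError):
            extract_inertial_stride(_cycle(10, 22), trace)  # 10% of 12 samples -> 1

    def test_noiseless_strides_match_truth(self, noiseless_trial):
        for side in ("left", "right"):
            anat = harmonize_axes(noiseless_trial.accel(side))
            hs = detect_heel_strikes_accel(anat)
            cycles = build_stride_cycles(hs, anat.fs, side=side)
            table = extract_inertial_trial(cycles, anat)
            truth = truth_strides(noiseless_trial, side)
            for v in ("st", "vm", "vm10", "mag_l", "mag_v", "mag_a", "imp_l", "imp_v", "imp_a"):
                assert np.max(np.abs(table[v].to_numpy() - truth[v].to_numpy())) < 1e-6, v
            for v in ("ang_l", "ang_a"):
                rel = np.abs(table[v].to_numpy() - truth[v].to_numpy()) / truth[v].to_numpy()
                assert np.max(rel) < 0.10, v

    def test_symmetric_trial_left_right_features_equal(self, noiseless_trial):
        tables = {}
        for side in ("left", "right"):
            anat = harmonize_axes(noiseless_trial.accel(side))
            cycles = build_stride_cycles(noiseless_trial.hs_times(side), anat.fs, side=side)
            tables[side] = extract_inertial_trial(cycles, anat)
        for v in ("vm", "vm10", "mag_l", "mag_v", "mag_a", "imp_l", "imp_v", "imp_a", "st"):
            assert np.allclose(tables["left"][v], tables["right"][v], atol=1e-6), v


class TestHeightNormalisation:
    def _feats(self):
        trace = _anat(np.zeros(1000), 2.0 * np.ones(1000), np.zeros(1000))
        return extract_inertial_stride(_cycle(100, 340), trace)

    def test_known_arithmetic(self):
        subject = SubjectMeta("H", 1.71, 87.1, "left")
        out = normalize_by_height(self._feats(), subject)
        assert out.vm == pytest.approx(1.0 / 1.71)

    def test_st_and_angles_unchanged(self):
        feats = self._feats()
        out = normalize_by_height(feats, SubjectMeta("H", 1.71, 87.1, "left"))
        assert out.st == feats.st
        assert out.ang_l == feats.ang_l

    def test_double_normalisation_rejected(self):
        subject = SubjectMeta("H", 1.71, 87.1, "left")
        once = normalize_by_height(self._feats(), subject)
        with pytest.raises(ParameterError):
            normalize_by_height(once, subject)
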