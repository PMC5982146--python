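import numpy as np
import pytest

from gaitkit import (
    build_stride_cycles,
    detect_heel_strikes_accel,
    extract_biomech_stride,
    harmonize_axes,
    normalize_by_weight,
)
from gaitkit.biomech_features import extract_biomech_trial
from gaitkit.exceptions import FeatureError, ParameterError
from gaitkit.gait_events import StrideCycle
from gaitkit.signal_io import BiomechTrace, SubjectMeta

from conftest import truth_strides


def _trace(vgrf, fs=200.0, **channels):
    n = len(vgrf)
    z = np.zeros(n)
    return BiomechTrace(
        t=np.arange(n) / fs,
        vgrf=np.asarray(vgrf, float),
        agrf=channels.get("agrf", z),
        kfm=channels.get("kfm", z),
        kam=channels.get("kam", z),
        fs=fs,
        side="left",
    )


def _cycle(hs, nxt, fs=200.0, stance_frac=0.6):
    return StrideCycle(
        side="left",
        hs_time=hs,
        next_hs_time=nxt,
        stance_end_time=hs + stance_frac * (nxt - hs),
        hs_index=int(round(hs * fs)),
        next_hs_index=int(round(nxt * fs)),
    )


def _two_hump_vgrf(n, first, second):
    """M-shaped stance: two humps with controlled apex values."""
    v = np.zeros(n)
    v[10:40] = first * np.sin(np.pi * np.arange(30) / 30)
    v[45:75] = second * np.sin(np.pi * np.arange(30) / 30)
    return v


class TestFirstPeakRule:
    def test_picks_first_hump_not_global_max(self):
        # second hump larger: the global-max rule would pick 1.15
        v = _two_hump_vgrf(240, 1.10, 1.15)
        feats = extract_biomech_stride(_cycle(0.0, 240 / 200), _trace(v))
        # oracle: manual scan for the earliest strict local max above threshold
        thr = 0.2 * v.max()
        manual = next(
            v[i] for i in range(1, len(v) - 1) if v[i] > v[i - 1] and v[i] > v[i + 1] and v[i] >= thr
        )
        assert feats.vgrf == pytest.approx(manual)
        assert feats.vgrf == pytest.approx(v[10:40].max())

    def test_unimodal_falls_back_to_stance_max(self):
        v = np.zeros(240)
        v[10:100] = 3.0 * np.sin(np.pi * np.arange(90) / 90)
        feats = extract_biomech_stride(_cycle(0.0, 1.2), _trace(v))
        assert feats.vgrf == pytest.approx(v[:144].max())

    def test_constant_zero_moment_gives_zero(self):
        v = _two_hump_vgrf(240, 1.1, 1.0)
        feats = extract_biomech_stride(_cycle(0.0, 1.2), _trace(v))
        assert feats.kfm == 0.0
        assert feats.kam == 0.0

    def test_vgrf1_never_exceeds_stance_max(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            v = np.abs(rng.normal(size=240)).cumsum() % 5 + 0.1
            feats = extract_biomech_stride(_cycle(0.0, 1.2), _trace(v))
            assert feats.vgrf <= v[:144].max() + 1e-12

    def test_stride_outside_trace_is_error(self):
        with pytest.raises(FeatureError):
            extract_biomech_stride(_cycle(5.0, 6.2), _trace(np.ones(240)))


class TestAgainstTruth:
    def test_noiseless_strides_match_truth_peaks(self, noiseless_trial):
        for side in ("left", "right"):
            anat = harmonize_axes(noiseless_trial.accel(side))
            hs = detect_heel_strikes_accel(anat)
            cycles = build_stride_cycles(hs, anat.fs, side=side)
            table = extract_biomech_trial(cycles, noiseless_trial.biomech(side))
            truth = truth_strides(noiseless_trial, side)
            for v in ("kfm", "kam", "agrf", "vgrf"):
                assert np.max(np.abs(table[v].to_numpy() - truth[v].to_numpy())) < 1e-6

    def test_time_offset_invariance(self, noiseless_trial):
        trace = noiseless_trial.biomech_left
        cycles = build_stride_cycles(noiseless_trial.hs_times("left"), trace.fs)
        base = extract_biomech_stride(cycles[0], trace)
        shifted_trace = BiomechTrace(
            t=trace.t + 100.0, vgrf=trace.vgrf, agrf=trace.agrf,
            kfm=trace.kfm, kam=trace.kam, fs=trace.fs, side="left",
        )
        c = cycles[0]
        shifted_cycle = StrideCycle(
            side=c.side, hs_time=c.hs_time + 100.0, next_hs_time=c.next_hs_time + 100.0,
            stance_end_time=c.stance_end_time + 100.0,
            hs_index=c.hs_index, next_hs_index=c.next_hs_index,
        )
        shifted = extract_biomech_stride(shifted_cycle, shifted_trace)
        assert shifted.as_dict() == pytest.approx(base.as_dict())


class TestWeightNormalisation:
    def test_known_arithmetic(self):
        feats = extract_biomech_stride(
            _cycle(0.0, 1.2), _trace(_two_hump_vgrf(240, 871.0, 800.0))
        )
        subject = SubjectMeta("W", 1.71, 87.1, "left")
        out = normalize_by_weight(feats, subject)
        assert out.vgrf == pytest.approx(10.0)

    def test_homogeneity_in_mass_and_force(self):
        v = _two_hump_vgrf(240, 900.0, 850.0)
        f1 = normalize_by_weight(
            extract_biomech_stride(_cycle(0.0, 1.2), _trace(v)),
            SubjectMeta("A", 1.7, 80.0, "left"),
        )
        f2 = normalize_by_weight(
            extract_biomech_stride(_cycle(0.0, 1.2), _trace(2 * v)),
            SubjectMeta("B", 1.7, 160.0, "left"),
        )
        assert f1.vgrf == pytest.approx(f2.vgrf)

    def test_double_normalisation_rejected(self):
        feats = extract_biomech_stride(_cycle(0.0, 1.2), _trace(_two_hump_vgrf(240, 1.1, 1.0)))
        subject = SubjectMeta("W", 1.71, 87.1, "left")
        once = normalize_by_weight(feats, subject)
        with pytest.raises(ParameterError):
            normalize_by_weight(once, subject)
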