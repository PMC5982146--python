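"""Synthetic bilateral gait trials with ground truth.

Generates quasi-periodic treadmill walking for one subject: two ankle
accelerometer traces (200 Hz, g-units, sensor frame) and per-limb
biomechanical traces (vGRF, aGRF, knee flexion/adduction moments), together
with a truth table holding every heel-strike time and every per-stride
feature value the generator controls.  The waveforms are minimal shapes that
reproduce the landmarks the analysis depends on:

* anterior acceleration: a damped-oscillation transient at each heel strike
  (the sharp peak used for step detection) over a slow tilt/swing baseline;
* vertical acceleration: 1 g gravity baseline, a heel-strike transient, and a
  small double-frequency "bounce";
* vGRF: an M-shaped double hump per stance with a steep initial rise, the
  first (weight-acceptance) peak amplitude being the controlled quantity;
* aGRF: braking (negative) then propulsive (positive) humps;
* knee moments: single early-stance peaks.

Peak apexes are snapped to the sampling grid so that noiseless extraction
recovers the truth values to machine precision.  Left and right limbs share
one stride-time sequence and are phase-offset by half a stride; an
``asymmetry`` ratio multiplies every surgical-limb amplitude, so setting it
to 1 with zero noise yields perfectly symmetric gait by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .signal_io import (
    G_CONST,
    MIRROR_SIDE,
    AccelTrace,
    BiomechTrace,
    SubjectMeta,
    write_accel_csv,
    write_biomech_csv,
    write_subjects_csv,
)

INERTIAL_VARS = [
    "vm",
    "vm10",
    "mag_l",
    "mag_v",
    "mag_a",
    "imp_l",
    "imp_v",
    "imp_a",
    "ang_l",
    "ang_a",
    "st",
]
BIOMECH_VARS = ["kfm", "kam", "agrf", "vgrf"]


def initial_window_samples(n_stride: int, frac: float = 0.10) -> int:
    """Length in samples of the 'initial fraction of the stride' window."""
    return int(round(frac * n_stride))


def stance_window_samples(n_stride: int, stance_frac: float = 0.60) -> int:
    """Length in samples of the stance window within a stride."""
    return int(round(stance_frac * n_stride))


@dataclass
class GaitSimParams:
    """Generator parameters.

    Amplitudes are expressed per variable's natural unit: accelerations in g,
    vGRF/aGRF peaks in body-weight multiples, knee moments in N·m/kg.
    ``asymmetry`` is the surgical/non-surgical amplitude ratio (1 = symmetric)
    applied to every peak amplitude on the surgical limb.
    """

    stride_time_mean: float = 1.15  # s
    stride_time_sd: float = 0.05  # s
    n_strides: int = 30  # heel strikes per limb
    fs: float = 200.0  # Hz
    # accelerometer waveform
    hs_peak_accel: float = 2.0  # g, anterior transient amplitude
    vert_transient_ratio: float = 0.8  # vertical transient = ratio * anterior
    lat_transient_ratio: float = 0.4
    transient_decay: float = 0.025  # s, exponential decay constant
    transient_freq: float = 18.0  # Hz, transient oscillation
    swing_amp: float = 0.01  # g, anterior swing sinusoid (2 cycles/stride)
    bounce_amp: float = 0.08  # g, vertical bounce (2 cycles/stride)
    tilt_amp_lat: float = 4.0  # deg, lateral shank-tilt program amplitude
    tilt_amp_ant: float = 3.0  # deg, anterior tilt program amplitude
    # biomechanical waveform
    vgrf_first_peak: float = 1.10  # body-weight multiples
    vgrf_second_ratio: float = 0.95  # second hump relative to first
    vgrf_valley_ratio: float = 0.72  # mid-stance valley relative to first
    vgrf_rise: float = 0.02  # s, initial steep rise to the first peak
    agrf_peak: float = 0.22  # body-weight multiples (propulsive)
    agrf_brake_ratio: float = 0.30  # braking hump relative to propulsive
    kfm_peak: float = 0.55  # N·m/kg
    kam_peak: float = 0.45  # N·m/kg
    stance_frac: float = 0.60  # stance fraction of the stride
    # variability and asymmetry
    asymmetry: float = 1.0  # surgical/non-surgical amplitude ratio
    accel_amp_cv: float = 0.03  # per-stride amplitude CV, accelerometer
    biomech_amp_cv: float = 0.03  # per-stride amplitude CV, force/moments
    noise_sd: float = 0.02  # g, additive accelerometer noise
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        if self.n_strides < 2:
            raise ParameterError("n_strides must be at least 2")
        if self.stride_time_mean <= 0:
            raise ParameterError("stride_time_mean must be positive")
        if self.stride_time_sd < 0:
            raise ParameterError("stride_time_sd must be non-negative")
        if self.asymmetry <= 0:
            raise ParameterError("asymmetry must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        if self.hs_peak_accel <= 0:
            raise ParameterError("hs_peak_accel must be positive")
        if self.vgrf_first_peak <= 0:
            raise ParameterError("vgrf_first_peak must be positive")
        if not 0 < self.stance_frac < 1:
            raise ParameterError("stance_frac must lie in (0, 1)")
        if self.transient_decay <= 0 or self.vgrf_rise <= 0:
            raise ParameterError("durations must be positive")


@dataclass
class SyntheticTrial:
    """One subject's simulated trial: traces plus the generating truth.

    ``truth`` has one row per heel strike and side; rows that start a
    complete stride carry the generating feature values (accelerations in g,
    forces in N, moments in N·m, angles in degrees, times in s); the final
    heel strike of each side carries NaNs.
    """

    subject: SubjectMeta
    params: GaitSimParams
    accel_left: AccelTrace
    accel_right: AccelTrace
    biomech_left: BiomechTrace
    biomech_right: BiomechTrace
    truth: pd.DataFrame

    def hs_times(self, side: str) -> np.ndarray:
        rows = self.truth[self.truth["side"] == side]
        return rows["hs_time"].to_numpy()

    def accel(self, side: str) -> AccelTrace:
        return self.accel_left if side == "left" else self.accel_right

    def biomech(self, side: str) -> BiomechTrace:
        return self.biomech_left if side == "left" else self.biomech_right

    def plot(self, side: str = "left", ax=None):
        """Quick-look plot of the anterior acceleration and vGRF with truth HS."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        acc = self.accel(side)
        bio = self.biomech(side)
        ax.plot(acc.t, acc.ay, lw=0.8, label="anterior accel (g)")
        ax.plot(bio.t, bio.vgrf / (self.subject.mass * G_CONST), lw=0.8, label="vGRF (BW)")
        for hs in self.hs_times(side):
            ax.axvline(hs, color="k", alpha=0.2, lw=0.5)
        ax.set_xlabel("time (s)")
        ax.legend(loc="upper right")
        return ax


def _stride_durations(params: GaitSimParams, rng: np.random.Generator) -> np.ndarray:
    """Stride durations in samples, shared by both limbs."""
    n = params.n_strides - 1
    d = rng.normal(params.stride_time_mean, params.stride_time_sd, size=n)
    d = np.clip(d, 0.6 * params.stride_time_mean, 1.4 * params.stride_time_mean)
    return np.round(d * params.fs).astype(int)


def _amp_factors(cv: float, n: int, rng: np.random.Generator) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    return 1.0 + cv * np.clip(rng.normal(size=n), -2.5, 2.5)


def _transient(u: np.ndarray, amp: float, decay: float, freq: float) -> np.ndarray:
    return amp * np.exp(-u / decay) * np.cos(2 * np.pi * freq * u)


def _bump(n_total: int, n0: int, n1: int, npk: int, amp: float) -> np.ndarray:
    """Smooth cosine bump over samples [n0, n1) with apex exactly at npk."""
    seg = np.zeros(n_total)
    k = np.arange(n0, npk + 1)
    if npk > n0:
        seg[k] = amp * 0.5 * (1 - np.cos(np.pi * (k - n0) / (npk - n0)))
    else:
        seg[npk] = amp
    k = np.arange(npk, n1)
    if n1 > npk + 1:
        seg[k] = amp * 0.5 * (1 + np.cos(np.pi * (k - npk) / (n1 - npk)))
    return seg


def _synth_accel_side(
    params: GaitSimParams,
    hs_idx: np.ndarray,
    d_samples: np.ndarray,
    fac: np.ndarray,
    amp_scale: float,
    n_total: int,
):
    """Clean anatomical-frame channels for one side plus per-stride truth.

    Returns (lat, vert, ant, truth_rows).  ``amp_scale`` is the asymmetry
    factor for this limb.
    """
    fs = params.fs
    lat = np.zeros(n_total)
    vert = np.ones(n_total)
    ant = np.zeros(n_total)

    deg = np.pi / 180.0
    # slow per-stride programs: tilt (1 cycle/stride, zero at HS) and
    # swing/bounce (2 cycles/stride, zero at HS)
    theta_l_full = np.zeros(n_total)
    theta_a_full = np.zeros(n_total)
    for k in range(len(d_samples)):
        s, e = hs_idx[k], hs_idx[k + 1]
        u = np.arange(e - s) / fs
        phase = 2 * np.pi * u / ((e - s) / fs)
        th_l = amp_scale * params.tilt_amp_lat * deg * np.sin(phase)
        th_a = amp_scale * params.tilt_amp_ant * deg * np.sin(phase)
        theta_l_full[s:e] = th_l
        theta_a_full[s:e] = th_a
        lat[s:e] = np.sin(th_l)
        vert[s:e] = np.cos(th_l) * np.cos(th_a) + params.bounce_amp * np.sin(2 * phase)
        ant[s:e] = np.cos(th_l) * np.sin(th_a) + params.swing_amp * np.sin(2 * phase)

    # heel-strike transients (damped oscillation, apex exactly at the HS sample)
    n_tr = int(round(0.25 * fs))
    for k, s in enumerate(hs_idx):
        stop = min(s + n_tr, n_total)
        u = np.arange(stop - s) / fs
        amp_a = params.hs_peak_accel * fac[k] * amp_scale
        shape = _transient(u, 1.0, params.transient_decay, params.transient_freq)
        ant[s:stop] += amp_a * shape
        vert[s:stop] += params.vert_transient_ratio * amp_a * shape
        lat[s:stop] += params.lat_transient_ratio * amp_a * shape

    # per-stride truth (g-units, degrees, seconds); np.add.reduce keeps the
    # many tiny-window reductions cheap
    def _mean(x: np.ndarray) -> float:
        return float(np.add.reduce(x)) / x.size

    def _sd(x: np.ndarray) -> float:
        d = x - _mean(x)
        return float(np.sqrt(_mean(d * d)))

    rows = []
    for k in range(len(d_samples)):
        s, e = hs_idx[k], hs_idx[k + 1]
        n_i = e - s
        amp_a = params.hs_peak_accel * fac[k] * amp_scale
        n10 = initial_window_samples(n_i)
        n_st = stance_window_samples(n_i, params.stance_frac)
        resid = np.abs(np.sqrt(lat[s:e] ** 2 + vert[s:e] ** 2 + ant[s:e] ** 2) - 1.0)
        row = {
            "hs_time": s / fs,
            "next_hs_time": e / fs,
            "st": n_i / fs,
            "mag_a": amp_a,
            "mag_v": 1.0 + params.vert_transient_ratio * amp_a,
            "mag_l": params.lat_transient_ratio * amp_a,
            "vm": float(np.sqrt(_mean(resid**2))),
            "vm10": float(np.sqrt(_mean(resid[:n10] ** 2))) if n10 >= 2 else np.nan,
            "imp_l": _sd(lat[s : s + n10]) if n10 >= 2 else np.nan,
            "imp_v": _sd(vert[s : s + n10]) if n10 >= 2 else np.nan,
            "imp_a": _sd(ant[s : s + n10]) if n10 >= 2 else np.nan,
            "ang_l": _sd(theta_l_full[s : s + n_st]) / deg,
            "ang_a": _sd(theta_a_full[s : s + n_st]) / deg,
        }
        rows.append(row)
    return lat, vert, ant, rows


def _synth_biomech_side(
    params: GaitSimParams,
    subject: SubjectMeta,
    hs_idx: np.ndarray,
    d_samples: np.ndarray,
    fac_b: np.ndarray,
    amp_scale: float,
    n_total: int,
):
    """Clean biomechanical channels (raw N and N·m) plus per-stride truth."""
    fs = params.fs
    vgrf = np.zeros(n_total)
    agrf = np.zeros(n_total)
    kfm = np.zeros(n_total)
    kam = np.zeros(n_total)
    bw = subject.mass * G_CONST

    n_hs = len(hs_idx)
    rows = []
    for k in range(n_hs):
        d_k = d_samples[k] if k < len(d_samples) else int(round(params.stride_time_mean * fs))
        s = hs_idx[k]
        sn = stance_window_samples(d_k, params.stance_frac)
        rise_n = max(2, int(round(params.vgrf_rise * fs)))
        if sn < rise_n + 8:
            raise ParameterError("stride too short for the configured vGRF shape")

        scale = fac_b[k] * amp_scale
        p1 = params.vgrf_first_peak * scale * bw
        p2 = params.vgrf_second_ratio * p1
        vmid = params.vgrf_valley_ratio * p1
        ap = params.agrf_peak * scale * bw
        kfm_amp = params.kfm_peak * scale * subject.mass
        kam_amp = params.kam_peak * scale * subject.mass

        stop = min(s + sn, n_total)
        seg = np.zeros(sn)
        kmid = int(round(0.45 * sn))
        k2 = int(round(0.75 * sn))
        ks = np.arange(sn)
        m = ks <= rise_n
        seg[m] = p1 * ks[m] / rise_n
        m = (ks > rise_n) & (ks <= kmid)
        seg[m] = vmid + (p1 - vmid) * 0.5 * (1 + np.cos(np.pi * (ks[m] - rise_n) / (kmid - rise_n)))
        m = (ks > kmid) & (ks <= k2)
        seg[m] = vmid + (p2 - vmid) * 0.5 * (1 - np.cos(np.pi * (ks[m] - kmid) / (k2 - kmid)))
        m = ks > k2
        seg[m] = p2 * 0.5 * (1 + np.cos(np.pi * (ks[m] - k2) / (sn - k2)))
        vgrf[s:stop] = seg[: stop - s]

        a_seg = _bump(sn, 0, sn // 2, int(round(0.25 * sn)), -params.agrf_brake_ratio * ap)
        a_seg += _bump(sn, sn // 2, sn, int(round(0.80 * sn)), ap)
        agrf[s:stop] = a_seg[: stop - s]

        kfm_seg = _bump(sn, 0, int(round(0.45 * sn)), int(round(0.15 * sn)), kfm_amp)
        kam_seg = _bump(sn, 0, int(round(0.50 * sn)), int(round(0.20 * sn)), kam_amp)
        kfm[s:stop] = kfm_seg[: stop - s]
        kam[s:stop] = kam_seg[: stop - s]

        if k < len(d_samples):
            rows.append({"vgrf": p1, "agrf": ap, "kfm": kfm_amp, "kam": kam_amp})
    return vgrf, agrf, kfm, kam, rows


def simulate_trial(params: GaitSimParams, subject: SubjectMeta) -> SyntheticTrial:
    """Generate one bilateral trial with truth annotations.

    Deterministic given ``params.seed``: identical parameters produce
    bit-identical traces and truth.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    fs = params.fs

    d_samples = _stride_durations(params, rng)
    fac = _amp_factors(params.accel_amp_cv, params.n_strides, rng)
    fac_b = _amp_factors(params.biomech_amp_cv, params.n_strides, rng)

    start = int(round(0.5 * fs))
    hs_left = start + np.concatenate([[0], np.cumsum(d_samples)])
    # constant half-stride phase offset keeps the two limbs' stride-time
    # sequences identical (required for the symmetry-null construction)
    half = int(round(0.5 * params.stride_time_mean * fs))
    hs_right = hs_left + half
    n_total = int(hs_right[-1] + round((params.stride_time_mean + 0.5) * fs))
    t = np.arange(n_total) / fs

    hs = {"left": hs_left, "right": hs_right}
    accel_traces = {}
    biomech_traces = {}
    truth_rows = []
    for side in ("left", "right"):
        amp_scale = params.asymmetry if side == subject.surgical_side else 1.0
        lat, vert, ant, acc_rows = _synth_accel_side(
            params, hs[side], d_samples, fac, amp_scale, n_total
        )
        vg, ag, kf, ka, bio_rows = _synth_biomech_side(
            params, subject, hs[side], d_samples, fac_b, amp_scale, n_total
        )
        if params.noise_sd > 0:
            lat = lat + rng.normal(0, params.noise_sd, n_total)
            vert = vert + rng.normal(0, params.noise_sd, n_total)
            ant = ant + rng.normal(0, params.noise_sd, n_total)
        flip = -1.0 if side == MIRROR_SIDE else 1.0
        accel_traces[side] = AccelTrace(
            t=t, ax=vert, ay=ant, az=flip * lat, fs=fs, side=side, frame="sensor"
        )
        biomech_traces[side] = BiomechTrace(
            t=t, vgrf=vg, agrf=ag, kfm=kf, kam=ka, fs=fs, side=side
        )
        for k, row in enumerate(acc_rows):
            full = {"side": side, "stride": k, **row, **bio_rows[k]}
            truth_rows.append(full)
        truth_rows.append(
            {"side": side, "stride": len(acc_rows), "hs_time": hs[side][-1] / fs}
        )

    truth = pd.DataFrame(truth_rows)
    return SyntheticTrial(
        subject=subject,
        params=params,
        accel_left=accel_traces["left"],
        accel_right=accel_traces["right"],
        biomech_left=biomech_traces["left"],
        biomech_right=biomech_traces["right"],
        truth=truth,
    )


def write_trial(trial: SyntheticTrial, out_dir, header_comment: Optional[str] = None) -> None:
    """Write a trial in the CSV dialects signal_io reads, plus a truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = trial.subject.subject_id
    for side in ("left", "right"):
        write_accel_csv(trial.accel(side), out_dir / f"{sid}_{side}_accel.csv", header_comment)
        write_biomech_csv(trial.biomech(side), out_dir / f"{sid}_{side}_biomech.csv", header_comment)
    trial.truth.to_csv(out_dir / f"{sid}_truth.csv", index=False)


# ---------------------------------------------------------------------------
# Cohort simulation with known feature -> target effects
# ---------------------------------------------------------------------------

#: Default linear effects used for demonstration cohorts, chosen so that each
#: biomechanical target is driven mainly by inertial variables of its own
#: direction (anterior for KFM/aGRF, lateral for KAM, vertical for vGRF) on
#: top of realistic baseline magnitudes.  Targets are weight-normalised
#: (N/kg, N·m/kg); features are height-normalised (g/m) or native units.
DEFAULT_EFFECT_SPEC = {
    "kfm": {"coef": {"mag_a": 0.25, "imp_a": 0.30, "mag_v": 0.05}, "intercept": 0.10, "noise_sd": 0.03},
    "kam": {"coef": {"mag_l": 0.60, "ang_l": 0.04}, "intercept": 0.05, "noise_sd": 0.03},
    "agrf": {"coef": {"mag_a": 0.80, "ang_a": 0.15}, "intercept": 0.80, "noise_sd": 0.08},
    "vgrf": {"coef": {"mag_v": 2.50, "st": -1.50}, "intercept": 9.0, "noise_sd": 0.30},
}


@dataclass
class SyntheticCohort:
    """A simulated cohort with subject-level truth features and targets.

    ``features``: per-subject trial-average inertial variables (acceleration
    features height-normalised, g/m); ``targets``: per-subject trial-average
    biomechanical variables (weight-normalised); ``summary``: the model-ready
    table with ``avg_*`` and ``si_*`` columns built from the generating truth.
    ``trials`` holds full :class:`SyntheticTrial` objects when traces were
    requested, else ``None`` placeholders.
    """

    subjects: list
    trials: list
    features: pd.DataFrame
    targets: pd.DataFrame
    summary: pd.DataFrame
    effect_spec: dict


def _subject_truth_features(params, subject, rng):
    """Per-side trial-mean inertial truth features for one subject.

    Synthesises the clean accelerometer signal (no trace objects) and averages
    the per-stride truth.  Returns (per-side dict of Series, d_samples, layout)
    where layout carries what a later full synthesis needs to be consistent.
    """
    fs = params.fs
    d_samples = _stride_durations(params, rng)
    fac = _amp_factors(params.accel_amp_cv, params.n_strides, rng)
    start = int(round(0.5 * fs))
    hs_left = start + np.concatenate([[0], np.cumsum(d_samples)])
    half = int(round(0.5 * params.stride_time_mean * fs))
    hs_right = hs_left + half
    n_total = int(hs_right[-1] + round((params.stride_time_mean + 0.5) * fs))
    per_side = {}
    for side, hs_idx in (("left", hs_left), ("right", hs_right)):
        amp_scale = params.asymmetry if side == subject.surgical_side else 1.0
        _, _, _, rows = _synth_accel_side(params, hs_idx, d_samples, fac, amp_scale, n_total)
        per_side[side] = {
            v: sum(r[v] for r in rows) / len(rows) for v in INERTIAL_VARS
        }
    return per_side


ACCEL_DERIVED = ["vm", "vm10", "mag_l", "mag_v", "mag_a", "imp_l", "imp_v", "imp_a"]


def _robinson(x_ns: float, x_s: float) -> float:
    return 100.0 * (x_ns - x_s) / (0.5 * (x_ns + x_s))


def simulate_cohort(
    n_subjects: int = 18,
    effect_spec: Optional[dict] = None,
    seed: int = 0,
    n_strides: int = 30,
    include_traces: bool = True,
    asymmetry_sd: float = 0.0,
    base_params: Optional[GaitSimParams] = None,
):
    """Simulate a cohort whose biomechanical targets follow known linear effects.

    Each subject receives an independent gait "profile" (transient amplitudes,
    tilt amplitudes, stride time, anthropometrics); the trial-average
    biomechanical targets are then generated as ``intercept + coef · features
    + N(0, noise_sd)`` per ``effect_spec`` entry, so regression-recovery tests
    have known coefficients.  ``effect_spec`` maps target name ('kfm', 'kam',
    'agrf', 'vgrf') to ``{'coef': {feature: beta}, 'intercept': b0,
    'noise_sd': sd}`` with targets weight-normalised and acceleration
    features height-normalised.

    With ``include_traces=False`` only the truth-level feature/target tables
    are produced (fast path for large simulation studies).
    """
    if n_subjects < 2:
        raise ParameterError("n_subjects must be at least 2")
    if effect_spec is None:
        effect_spec = DEFAULT_EFFECT_SPEC
    if not effect_spec:
        raise ParameterError("effect_spec must not be empty")
    for tgt, spec in effect_spec.items():
        if tgt not in BIOMECH_VARS:
            raise ParameterError(f"unknown target {tgt!r} in effect_spec")
        if not spec.get("coef"):
            raise ParameterError(f"effect_spec[{tgt!r}] has no coefficients")
        for f in spec["coef"]:
            if f not in INERTIAL_VARS:
                raise ParameterError(f"unknown feature {f!r} in effect_spec[{tgt!r}]")

    master = np.random.default_rng(seed)
    base = base_params if base_params is not None else GaitSimParams()

    subjects, trials, feat_rows, tgt_rows, sum_rows = [], [], [], [], []
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        height = float(np.clip(master.normal(1.714, 0.084), 1.45, 2.00))
        mass = float(np.clip(master.normal(87.1, 17.5), 45.0, 140.0))
        age = float(master.normal(66.5, 7.7))
        surgical = "left" if master.random() < 0.5 else "right"
        subject = SubjectMeta(sid, height, mass, surgical, age=age)

        asym = 1.0 if asymmetry_sd == 0 else float(np.clip(master.normal(1.0, asymmetry_sd), 0.5, 1.5))
        params = replace(
            base,
            n_strides=n_strides,
            stride_time_mean=float(np.clip(master.normal(1.15, 0.08), 0.95, 1.35)),
            hs_peak_accel=float(np.clip(master.normal(2.0, 0.35), 0.8, 3.5)),
            vert_transient_ratio=float(np.clip(master.normal(0.8, 0.15), 0.3, 1.3)),
            lat_transient_ratio=float(np.clip(master.normal(0.4, 0.10), 0.1, 0.8)),
            transient_decay=float(np.clip(master.normal(0.025, 0.005), 0.015, 0.045)),
            tilt_amp_lat=float(np.clip(master.normal(4.0, 1.0), 1.0, 8.0)),
            tilt_amp_ant=float(np.clip(master.normal(3.0, 0.8), 1.0, 7.0)),
            bounce_amp=float(np.clip(master.normal(0.08, 0.02), 0.02, 0.16)),
            asymmetry=asym,
            biomech_amp_cv=0.0,
            seed=int(master.integers(2**31)),
        )

        feat_rng = np.random.default_rng(params.seed)
        per_side = _subject_truth_features(params, subject, feat_rng)
        feats = {
            v: (per_side["left"][v] + per_side["right"][v]) / 2.0 for v in INERTIAL_VARS
        }
        for f in ACCEL_DERIVED:
            feats[f] = feats[f] / height  # height normalisation, g/m

        targets = {}
        for tgt in BIOMECH_VARS:
            if tgt in effect_spec:
                spec = effect_spec[tgt]
                y = spec.get("intercept", 0.0)
                for f, beta in spec["coef"].items():
                    y += beta * feats[f]
                y += master.normal(0.0, spec.get("noise_sd", 0.0))
            else:
                defaults = {"kfm": base.kfm_peak, "kam": base.kam_peak,
                            "agrf": base.agrf_peak * G_CONST,
                            "vgrf": base.vgrf_first_peak * G_CONST}
                y = defaults[tgt]
            targets[tgt] = float(max(y, 1e-3))

        # non-surgical amplitude so that the across-limb average equals the target
        ns_scale = 2.0 / (1.0 + asym)
        trial_params = replace(
            params,
            kfm_peak=targets["kfm"] * ns_scale,
            kam_peak=targets["kam"] * ns_scale,
            agrf_peak=targets["agrf"] * ns_scale / G_CONST,
            vgrf_first_peak=targets["vgrf"] * ns_scale / G_CONST,
        )

        trial = simulate_trial(trial_params, subject) if include_traces else None

        ns, s = subject.nonsurgical_side, subject.surgical_side
        srow = {"subject_id": sid}
        for v in INERTIAL_VARS:
            srow[f"avg_{v}"] = feats[v]
            srow[f"si_{v}"] = _robinson(per_side[ns][v], per_side[s][v])
        for v in BIOMECH_VARS:
            srow[f"avg_{v}"] = targets[v]
            srow[f"si_{v}"] = _robinson(targets[v] * ns_scale, targets[v] * ns_scale * asym)
        srow["n_strides_left"] = n_strides - 1
        srow["n_strides_right"] = n_strides - 1

        subjects.append(subject)
        trials.append(trial)
        feat_rows.append(pd.Series(feats, name=sid))
        tgt_rows.append(pd.Series(targets, name=sid))
        sum_rows.append(srow)

    features = pd.DataFrame(feat_rows)
    features.index.name = "subject_id"
    targets_df = pd.DataFrame(tgt_rows)
    targets_df.index.name = "subject_id"
    summary = pd.DataFrame(sum_rows).set_index("subject_id").reset_index()
    return SyntheticCohort(
        subjects=subjects,
        trials=trials,
        features=features,
        targets=targets_df,
        summary=summary,
        effect_spec=effect_spec,
    )


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write every trial plus subjects.csv into a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_subjects_csv(cohort.subjects, out_dir / "subjects.csv")
    for trial in cohort.trials:
        if trial is not None:
            write_trial(trial, out_dir)
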