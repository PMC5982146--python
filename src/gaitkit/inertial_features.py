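"""Per-stride inertial gait variables from anatomical-frame acceleration.

Eleven variables per stride, all computed from the 3-axis ankle signal:

======  ==============================================================
VM      RMS of the gravity-removed vector magnitude over the stride
VM10    the same over the initial 10% of the stride
MAG-d   maximum absolute directional acceleration in a short window
        after heel strike (d in lateral, vertical, anterior)
IMP-d   standard deviation of directional acceleration over the
        initial 10% of the stride (the "heel-strike impulse")
ANG-d   standard deviation of the gravity-referenced shank tilt angle
        over the stance window, lateral and anterior, in degrees
ST      heel-strike-to-heel-strike time
======  ==============================================================

"Residual acceleration" is the per-sample deviation of the acceleration
vector magnitude from 1 g — zero for a stationary (or purely rotating)
sensor.  Tilt angles come from low-pass-filtered channels (2nd-order
zero-phase Butterworth, 3 Hz) so that heel-strike transients do not
masquerade as orientation change.  Height normalisation divides every
acceleration-derived variable by body height; ST and angles are unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .exceptions import FeatureError, ParameterError
from .gait_events import StrideCycle
from .signal_io import AccelTrace, SubjectMeta
from .synthetic_gait import initial_window_samples, stance_window_samples

INERTIAL_FEATURE_NAMES = [
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

#: Acceleration-derived features (divided by height during normalisation).
HEIGHT_NORMALIZED = ["vm", "vm10", "mag_l", "mag_v", "mag_a", "imp_l", "imp_v", "imp_a"]

DEFAULT_HS_WINDOW = 0.10  # s, MAG-* search window after heel strike
DEFAULT_TILT_CUTOFF = 3.0  # Hz, tilt low-pass cutoff
DEFAULT_INITIAL_FRAC = 0.10


@dataclass
class InertialFeatures:
    """One stride's eleven inertial variables (g-units until normalised)."""

    vm: float
    vm10: float
    mag_l: float
    mag_v: float
    mag_a: float
    imp_l: float
    imp_v: float
    imp_a: float
    ang_l: float
    ang_a: float
    st: float
    stride: StrideCycle
    normalized: bool = False

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in INERTIAL_FEATURE_NAMES}


def residual_magnitude(lat: np.ndarray, vert: np.ndarray, ant: np.ndarray) -> np.ndarray:
    """Per-sample gravity-removed vector magnitude, | ||a|| - 1 g |, in g."""
    return np.abs(np.sqrt(np.asarray(lat) ** 2 + np.asarray(vert) ** 2 + np.asarray(ant) ** 2) - 1.0)


def tilt_angles(
    lat: np.ndarray,
    vert: np.ndarray,
    ant: np.ndarray,
    fs: float,
    cutoff: float = DEFAULT_TILT_CUTOFF,
) -> tuple[np.ndarray, np.ndarray]:
    """Gravity-referenced tilt-angle series (lateral, anterior) in degrees.

    The gravity direction is estimated by low-pass filtering the channels;
    tilt = atan2(filtered directional component, filtered vertical).
    A near-zero filtered magnitude (free fall) is rejected.
    """
    if fs <= 0 or cutoff <= 0:
        raise ParameterError("fs and cutoff must be positive")
    n = len(vert)
    if cutoff < fs / 2 and n > 15:
        b, a = butter(2, cutoff / (fs / 2))
        lat_lp = filtfilt(b, a, lat)
        vert_lp = filtfilt(b, a, vert)
        ant_lp = filtfilt(b, a, ant)
    else:  # segment too short to filter; use raw channels
        lat_lp, vert_lp, ant_lp = np.asarray(lat), np.asarray(vert), np.asarray(ant)
    mag = np.sqrt(lat_lp**2 + vert_lp**2 + ant_lp**2)
    if np.any(mag < 1e-6):
        raise FeatureError("filtered acceleration magnitude near zero (free fall?)")
    lateral = np.degrees(np.arctan2(lat_lp, vert_lp))
    anterior = np.degrees(np.arctan2(ant_lp, vert_lp))
    return lateral, anterior


def _window_checks(cycle: StrideCycle, trace: AccelTrace, initial_frac: float):
    n_stride = cycle.n_samples
    if cycle.hs_index < 0 or cycle.next_hs_index > len(trace):
        raise FeatureError("stride lies outside the trace")
    n10 = initial_window_samples(n_stride, initial_frac)
    if n10 < 2:
        raise FeatureError(
            f"initial {initial_frac:.0%} window is {n10} samples; need at least 2"
        )
    return n_stride, n10


def extract_inertial_stride(
    cycle: StrideCycle,
    trace: AccelTrace,
    hs_window: float = DEFAULT_HS_WINDOW,
    initial_frac: float = DEFAULT_INITIAL_FRAC,
    stance_frac: float = 0.60,
    tilt_cutoff: float = DEFAULT_TILT_CUTOFF,
    _tilt: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> InertialFeatures:
    """Extract the eleven inertial variables for one stride (unnormalised).

    All windows are index-based on the half-open stride interval
    ``[hs_index, next_hs_index)``.  ``_tilt`` accepts precomputed full-trace
    tilt series so trial-level extraction filters only once.
    """
    if hs_window <= 0:
        raise ParameterError("hs_window must be positive")
    n_stride, n10 = _window_checks(cycle, trace, initial_frac)
    s, e = cycle.hs_index, cycle.next_hs_index
    lat, vert, ant = trace.lateral, trace.vertical, trace.anterior

    resid = residual_magnitude(lat[s:e], vert[s:e], ant[s:e])
    vm = float(np.sqrt(np.mean(resid**2)))
    vm10 = float(np.sqrt(np.mean(resid[:n10] ** 2)))

    w = min(e, s + max(2, int(round(hs_window * trace.fs))))
    mag_l = float(np.max(np.abs(lat[s:w])))
    mag_v = float(np.max(np.abs(vert[s:w])))
    mag_a = float(np.max(np.abs(ant[s:w])))

    imp_l = float(np.std(lat[s : s + n10]))
    imp_v = float(np.std(vert[s : s + n10]))
    imp_a = float(np.std(ant[s : s + n10]))

    if _tilt is None:
        _tilt = tilt_angles(lat, vert, ant, trace.fs, tilt_cutoff)
    n_st = stance_window_samples(n_stride, stance_frac)
    ang_l = float(np.std(_tilt[0][s : s + n_st]))
    ang_a = float(np.std(_tilt[1][s : s + n_st]))

    return InertialFeatures(
        vm=vm,
        vm10=vm10,
        mag_l=mag_l,
        mag_v=mag_v,
        mag_a=mag_a,
        imp_l=imp_l,
        imp_v=imp_v,
        imp_a=imp_a,
        ang_l=ang_l,
        ang_a=ang_a,
        st=n_stride / trace.fs,
        stride=cycle,
    )


def normalize_by_height(features: InertialFeatures, subject: SubjectMeta) -> InertialFeatures:
    """Divide acceleration-derived variables by height (m) -> g/m.

    ST (s) and the tilt-angle SDs (degrees) are not height-dependent and are
    left unchanged.  Normalising twice is a state error.
    """
    if subject.height <= 0:
        raise ParameterError("height must be positive")
    if features.normalized:
        raise ParameterError("features are already height-normalised")
    updates = {k: getattr(features, k) / subject.height for k in HEIGHT_NORMALIZED}
    return replace(features, normalized=True, **updates)


def extract_inertial_trial(
    cycles: list[StrideCycle],
    trace: AccelTrace,
    subject: Optional[SubjectMeta] = None,
    hs_window: float = DEFAULT_HS_WINDOW,
    initial_frac: float = DEFAULT_INITIAL_FRAC,
    stance_frac: float = 0.60,
    tilt_cutoff: float = DEFAULT_TILT_CUTOFF,
) -> pd.DataFrame:
    """Per-stride inertial feature table for one limb.

    Filters the tilt series once for the whole trace, then extracts every
    stride; normalises by height when ``subject`` is given.
    """
    tilt = tilt_angles(trace.lateral, trace.vertical, trace.anterior, trace.fs, tilt_cutoff)
    rows = []
    for k, cyc in enumerate(cycles):
        feats = extract_inertial_stride(
            cyc,
            trace,
            hs_window=hs_window,
            initial_frac=initial_frac,
            stance_frac=stance_frac,
            tilt_cutoff=tilt_cutoff,
            _tilt=tilt,
        )
        if subject is not None:
            feats = normalize_by_height(feats, subject)
        rows.append(
            {
                "side": cyc.side,
                "stride": k,
                "hs_time": cyc.hs_time,
                "next_hs_time": cyc.next_hs_time,
                **feats.as_dict(),
            }
        )
    return pd.DataFrame(rows)
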