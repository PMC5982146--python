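"""Gait event detection and stride segmentation.

Heel strikes are the sharp transients in the anterior ankle acceleration;
step starts are recovered independently from the vertical ground reaction
force as upward crossings of a fraction (default 20%) of the trace maximum.
The two detectors cross-validate each other; strides are heel-strike to
next-heel-strike intervals of one limb, with stance approximated as a fixed
fraction of the stride.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .exceptions import DetectionError, ParameterError
from .signal_io import AccelTrace, BiomechTrace

#: Default minimum spacing between heel strikes (s); cadence ceiling of
#: roughly 150 strides/min.
DEFAULT_MIN_INTERVAL = 0.4
#: Default peak prominence (g) on height-unnormalised anterior acceleration.
DEFAULT_MIN_PROMINENCE = 0.5
#: Default step-start threshold as a fraction of the vGRF trace maximum.
DEFAULT_THRESHOLD_FRAC = 0.20
#: Default stance fraction of the stride.
DEFAULT_STANCE_FRAC = 0.60


@dataclass
class StrideCycle:
    """One limb's heel-strike-to-heel-strike interval.

    Sample indices are 0-based and the window is half-open ``[hs, next_hs)``.
    """

    side: str
    hs_time: float
    next_hs_time: float
    stance_end_time: float
    hs_index: int
    next_hs_index: int

    def __post_init__(self) -> None:
        if not self.hs_time < self.stance_end_time < self.next_hs_time:
            raise ParameterError(
                "require hs_time < stance_end_time < next_hs_time, got "
                f"{self.hs_time}, {self.stance_end_time}, {self.next_hs_time}"
            )

    @property
    def stride_time(self) -> float:
        return self.next_hs_time - self.hs_time

    @property
    def n_samples(self) -> int:
        return self.next_hs_index - self.hs_index


def detect_heel_strikes_accel(
    trace: AccelTrace,
    min_interval: float = DEFAULT_MIN_INTERVAL,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> np.ndarray:
    """Heel-strike times from anterior-acceleration peaks.

    Returns the times of local maxima of the anterior channel with prominence
    at least ``min_prominence`` (g) and pairwise spacing at least
    ``min_interval`` (s), strictly increasing.  An empty result is a warning,
    not an error.
    """
    if min_interval <= 0 or min_prominence <= 0:
        raise ParameterError("min_interval and min_prominence must be positive")
    anterior = trace.anterior  # raises if not anatomical
    if trace.duration < 2 * min_interval:
        raise ParameterError(
            f"trace duration {trace.duration:.3g} s is below 2x min_interval"
        )
    distance = max(1, int(round(min_interval * trace.fs)))
    idx, _ = find_peaks(anterior, prominence=min_prominence, distance=distance)
    if len(idx) == 0:
        warnings.warn("no heel-strike peaks found", stacklevel=2)
    return trace.t[idx]


def detect_steps_grf(
    trace: BiomechTrace,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
    min_gap: float = DEFAULT_MIN_INTERVAL,
) -> np.ndarray:
    """Step-start times from the vertical ground reaction force.

    A step starts at the first sample at or above ``threshold_frac`` times
    the trace maximum following a below-threshold sample (upward crossing at
    sample resolution), debounced by ``min_gap`` seconds.
    """
    if not 0 < threshold_frac < 1:
        raise ParameterError("threshold_frac must lie in (0, 1)")
    vgrf = trace.vgrf
    vmax = float(np.max(vgrf))
    if vmax <= 0:
        raise DetectionError("vGRF trace has no positive samples")
    thr = threshold_frac * vmax
    above = vgrf >= thr
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if len(crossings) == 0:
        return np.array([])
    gap = max(1, int(round(min_gap * trace.fs)))
    kept = [crossings[0]]
    for c in crossings[1:]:
        if c - kept[-1] >= gap:
            kept.append(c)
    return trace.t[np.asarray(kept)]


@dataclass
class EventMatchReport:
    """Agreement between two sorted event lists (greedy nearest matching)."""

    n_matched: int
    n_missed: int  # reference events with no candidate within tol
    n_spurious: int  # candidate events matched to nothing
    mean_abs_dt: float  # s, over matched pairs

    @property
    def match_rate(self) -> float:
        total = self.n_matched + self.n_missed
        return self.n_matched / total if total else float("nan")


def validate_events(
    accel_hs: np.ndarray, grf_hs: np.ndarray, tol: float = 0.05
) -> EventMatchReport:
    """Match accelerometer heel strikes against GRF step starts.

    Greedy nearest-neighbour matching within ``tol`` seconds; each event is
    used at most once.  ``accel_hs`` plays the role of the reference list.
    """
    a = np.sort(np.asarray(accel_hs, dtype=float))
    b = np.sort(np.asarray(grf_hs, dtype=float))
    pairs = []
    for i, ta in enumerate(a):
        for j, tb in enumerate(b):
            d = abs(tb - ta)
            if d <= tol:
                pairs.append((d, i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    dts = []
    for d, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        dts.append(d)
    n_matched = len(dts)
    return EventMatchReport(
        n_matched=n_matched,
        n_missed=len(a) - n_matched,
        n_spurious=len(b) - n_matched,
        mean_abs_dt=float(np.mean(dts)) if dts else float("nan"),
    )


def build_stride_cycles(
    hs_times: np.ndarray,
    fs: float,
    stance_frac: float = DEFAULT_STANCE_FRAC,
    side: str = "left",
) -> list[StrideCycle]:
    """One :class:`StrideCycle` per consecutive heel-strike pair.

    ``stance_end_time = hs + stance_frac * (next_hs - hs)``.  Fewer than two
    events yields an empty list with a warning.
    """
    if not 0 < stance_frac < 1:
        raise ParameterError("stance_frac must lie in (0, 1)")
    hs = np.asarray(hs_times, dtype=float)
    if len(hs) < 2:
        warnings.warn("fewer than 2 heel strikes; no strides built", stacklevel=2)
        return []
    if np.any(np.diff(hs) <= 0):
        raise ParameterError("heel-strike times must be strictly increasing")
    cycles = []
    for a, b in zip(hs[:-1], hs[1:]):
        cycles.append(
            StrideCycle(
                side=side,
                hs_time=float(a),
                next_hs_time=float(b),
                stance_end_time=float(a + stance_frac * (b - a)),
                hs_index=int(round(a * fs)),
                next_hs_index=int(round(b * fs)),
            )
        )
    return cycles
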