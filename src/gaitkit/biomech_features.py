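"""Per-stride biomechanical gait variables.

Four kinetic variables per stride: the early-stance maxima of the knee
flexion moment (KFM) and knee adduction moment (KAM), the maximum anterior
ground reaction force over the stride (aGRF), and the first vertical-GRF
peak (vGRF) — the weight-acceptance peak of the M-shaped stance profile,
identified as the earliest strict local maximum within stance above the
step-detection threshold.  Normalisation divides forces and moments by body
mass (N/kg, N·m/kg).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import FeatureError, ParameterError
from .gait_events import DEFAULT_THRESHOLD_FRAC, StrideCycle
from .signal_io import BiomechTrace, SubjectMeta

BIOMECH_FEATURE_NAMES = ["kfm", "kam", "agrf", "vgrf"]


@dataclass
class BiomechFeatures:
    """One stride's biomechanical variables (raw N, N·m until normalised)."""

    kfm: float
    kam: float
    agrf: float
    vgrf: float
    stride: StrideCycle
    normalized: bool = False

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in BIOMECH_FEATURE_NAMES}


def _first_local_max_above(x: np.ndarray, threshold: float) -> Optional[int]:
    """Index of the earliest sample strictly greater than both neighbours and
    at or above ``threshold``; None if no such sample exists."""
    for i in range(1, len(x) - 1):
        if x[i] > x[i - 1] and x[i] > x[i + 1] and x[i] >= threshold:
            return i
    return None


def extract_biomech_stride(
    stride: StrideCycle,
    trace: BiomechTrace,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
) -> BiomechFeatures:
    """Extract the four biomechanical variables for one stride (unnormalised).

    KFM and KAM are searched over the stance window (their loading-response
    peaks occur in early stance), aGRF over the whole stride (the propulsive
    peak occurs in late stance).  The vGRF first peak falls back to the
    stance maximum when the profile is unimodal.
    """
    # the stride interval is half-open, so next_hs_time may be one step past
    # the final sample
    if stride.hs_time < trace.t[0] - 1e-9 or stride.next_hs_time > trace.t[-1] + 1.0 / trace.fs + 1e-9:
        raise FeatureError(
            f"stride [{stride.hs_time}, {stride.next_hs_time}) lies outside the trace"
        )
    t = trace.t
    stride_mask = (t >= stride.hs_time) & (t < stride.next_hs_time)
    stance_mask = (t >= stride.hs_time) & (t < stride.stance_end_time)
    if stance_mask.sum() < 3:
        raise FeatureError("stance window too short for feature extraction")

    kfm = float(np.max(trace.kfm[stance_mask]))
    kam = float(np.max(trace.kam[stance_mask]))
    agrf = float(np.max(trace.agrf[stride_mask]))

    vgrf_stance = trace.vgrf[stance_mask]
    thr = threshold_frac * float(np.max(trace.vgrf))
    i = _first_local_max_above(vgrf_stance, thr)
    vgrf1 = float(vgrf_stance[i]) if i is not None else float(np.max(vgrf_stance))

    return BiomechFeatures(kfm=kfm, kam=kam, agrf=agrf, vgrf=vgrf1, stride=stride)


def normalize_by_weight(features: BiomechFeatures, subject: SubjectMeta) -> BiomechFeatures:
    """Divide forces and moments by body mass (kg) -> N/kg, N·m/kg."""
    if subject.mass <= 0:
        raise ParameterError("mass must be positive")
    if features.normalized:
        raise ParameterError("features are already weight-normalised")
    return replace(
        features,
        kfm=features.kfm / subject.mass,
        kam=features.kam / subject.mass,
        agrf=features.agrf / subject.mass,
        vgrf=features.vgrf / subject.mass,
        normalized=True,
    )


def extract_biomech_trial(
    cycles: list[StrideCycle],
    trace: BiomechTrace,
    subject: Optional[SubjectMeta] = None,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
) -> pd.DataFrame:
    """Per-stride biomechanical feature table for one limb.

    Normalises by body mass when ``subject`` is given.  Columns: side,
    stride, hs_time, next_hs_time, kfm, kam, agrf, vgrf.
    """
    rows = []
    for k, cyc in enumerate(cycles):
        feats = extract_biomech_stride(cyc, trace, threshold_frac)
        if subject is not None:
            feats = normalize_by_weight(feats, subject)
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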