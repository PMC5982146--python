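"""Trial-level summaries: averages, Robinson Symmetry Index, outlier flags.

Per-stride features from both limbs are summarised per trial as (a) the
arithmetic mean over all retained strides of both limbs and (b) a Symmetry
Index per variable.  The SI follows Robinson's formulation with the
surgical/non-surgical convention used for unilateral knee-replacement
cohorts::

    SI = 100 * (x_nonsurgical - x_surgical) / (0.5 * (x_nonsurgical + x_surgical))

so SI = 0 means perfect inter-limb symmetry and positive SI means the
surgical limb is the smaller one.  By default SI is computed per matched
stride pair (each surgical-limb stride paired with the non-surgical stride
whose interval encloses its heel strike) and averaged; a trial-mean-based
variant is available.

Outlier subjects are flagged from the cohort distribution of the four
trial-average biomechanical variables using the scaled median absolute
deviation (scale 1.4826, cutoff 3 by default).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .exceptions import ParameterError, SummaryError
from .signal_io import SubjectMeta

MAD_SCALE = 1.4826  # consistency factor for normal data

BIOMECH_VARS = ["kfm", "kam", "agrf", "vgrf"]
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
ALL_VARS = INERTIAL_VARS + BIOMECH_VARS


def trial_average(values: Iterable[float]) -> float:
    """Arithmetic mean over all retained strides (both limbs pooled)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise SummaryError("cannot average an empty set of strides")
    return float(np.mean(arr))


def symmetry_index(nonsurgical_mean: float, surgical_mean: float) -> float:
    """Robinson Symmetry Index in percent.

    Undefined (NaN) when the paired values sum to zero.
    """
    denom = 0.5 * (nonsurgical_mean + surgical_mean)
    if denom == 0:
        return float("nan")
    return 100.0 * (nonsurgical_mean - surgical_mean) / denom


def _pair_strides(ns_df: pd.DataFrame, s_df: pd.DataFrame) -> list[tuple[int, int]]:
    """Pair strides across limbs by ordinal position.

    The limbs walk in antiphase, so the i-th stride of each limb belongs to
    the i-th gait cycle; enclosure-based pairing is ambiguous (a heel strike
    sits near the midpoint of the contralateral stride) and would shift the
    pairing by one cycle on one side.  Both tables must be time-ordered.
    """
    n = min(len(ns_df), len(s_df))
    return [(i, i) for i in range(n)]


def summarize_trial(
    stride_features: pd.DataFrame,
    subject: SubjectMeta,
    si_mode: str = "stride",
    variables: Optional[list[str]] = None,
) -> pd.Series:
    """Summarise a per-stride feature table into one trial row.

    ``stride_features`` must carry ``side``, ``hs_time``, ``next_hs_time``
    and the feature columns (typically the 11 inertial plus 4 biomechanical
    variables, already normalised).  Returns a Series with ``avg_<var>``,
    ``si_<var>``, and per-side stride counts.

    ``si_mode='stride'`` averages per-pair Symmetry Indices over stride
    pairs matched by ordinal position (i-th stride of each limb);
    ``si_mode='trial'`` applies the SI formula to the per-limb trial means.
    """
    if si_mode not in ("stride", "trial"):
        raise ParameterError("si_mode must be 'stride' or 'trial'")
    if variables is None:
        variables = [v for v in ALL_VARS if v in stride_features.columns]
    if stride_features.empty:
        raise SummaryError("no strides to summarise")

    ns_side = subject.nonsurgical_side
    s_side = subject.surgical_side
    ns_df = stride_features[stride_features["side"] == ns_side].reset_index(drop=True)
    s_df = stride_features[stride_features["side"] == s_side].reset_index(drop=True)
    if ns_df.empty or s_df.empty:
        raise SummaryError("need at least one stride per limb")

    out = {"subject_id": subject.subject_id}
    for v in variables:
        out[f"avg_{v}"] = trial_average(stride_features[v])

    if si_mode == "trial":
        for v in variables:
            out[f"si_{v}"] = symmetry_index(float(ns_df[v].mean()), float(s_df[v].mean()))
    else:
        pairs = _pair_strides(ns_df, s_df)
        if not pairs:
            warnings.warn(
                "no stride pairs matched; falling back to trial-mean SI", stacklevel=2
            )
            for v in variables:
                out[f"si_{v}"] = symmetry_index(float(ns_df[v].mean()), float(s_df[v].mean()))
        else:
            for v in variables:
                sis = [
                    symmetry_index(float(ns_df[v].iloc[i]), float(s_df[v].iloc[j]))
                    for i, j in pairs
                ]
                out[f"si_{v}"] = float(np.nanmean(sis))

    out["n_strides_left"] = int((stride_features["side"] == "left").sum())
    out["n_strides_right"] = int((stride_features["side"] == "right").sum())
    return pd.Series(out)


def flag_outlier_subjects(
    summary: pd.DataFrame,
    cutoff: float = 3.0,
    variables: Optional[list[str]] = None,
) -> pd.Series:
    """Flag subjects whose biomechanical trial averages are MAD outliers.

    A subject is flagged when any of the checked variables deviates from the
    cohort median by more than ``cutoff`` times the scaled MAD (1.4826 x
    median absolute deviation).  By default only the four biomechanical
    averages are checked — the clinically meaningful exclusion signal.
    Variables with zero MAD are skipped with a warning.
    """
    if len(summary) < 3:
        raise ParameterError("need at least 3 subjects to flag outliers")
    if cutoff <= 0:
        raise ParameterError("cutoff must be positive")
    if variables is None:
        variables = [f"avg_{v}" for v in BIOMECH_VARS if f"avg_{v}" in summary.columns]
    flags = pd.Series(False, index=summary.index)
    for col in variables:
        x = summary[col].to_numpy(dtype=float)
        med = np.median(x)
        mad = MAD_SCALE * np.median(np.abs(x - med))
        if mad == 0:
            warnings.warn(f"{col}: zero MAD, variable skipped", stacklevel=2)
            continue
        flags |= np.abs(x - med) > cutoff * mad
    return flags
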