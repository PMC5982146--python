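"""Trace and metadata I/O plus bilateral axis harmonisation.

Ankle-worn accelerometers are mounted mirror-symmetrically on the two shanks:
the sensor X-axis points up the shank on both sides, but the Y/Z axes point in
opposite directions on the left and right legs.  :func:`harmonize_axes` maps
both sensors into one anatomical frame (vertical = up the shank, anterior =
walking direction, lateral = away from the body midline) by sign-flipping the
lateral channel on one configured side.

Acceleration is expressed in g throughout (``G_CONST`` converts to SI where
needed).  The interchange format is plain CSV with a fixed header; lines
starting with ``#`` are treated as comments so that provenance headers survive
round trips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import FormatError, ParameterError

#: Standard gravity, m/s^2, used wherever g-units meet SI units.
G_CONST = 9.80665

#: Side whose lateral sensor axis points toward the midline and is therefore
#: sign-flipped during harmonisation.  See the mounting-convention note in
#: the methods documentation.
MIRROR_SIDE = "left"

SIDES = ("left", "right")

ACCEL_COLUMNS = ["time", "ax", "ay", "az"]
BIOMECH_COLUMNS = ["time", "vgrf", "agrf", "kfm", "kam"]

#: Max deviation of a timestep from 1/fs before sampling counts as non-uniform.
UNIFORMITY_TOL = 1e-6


def _check_side(side: str) -> str:
    if side not in SIDES:
        raise ParameterError(f"side must be 'left' or 'right', got {side!r}")
    return side


def _infer_fs(t: np.ndarray) -> float:
    if len(t) < 2:
        raise FormatError("cannot infer sampling rate from fewer than 2 samples")
    dt = np.diff(t)
    fs = 1.0 / float(np.median(dt))
    if np.any(np.abs(dt - 1.0 / fs) > UNIFORMITY_TOL):
        raise FormatError(
            f"non-uniform sampling: max deviation "
            f"{np.max(np.abs(dt - 1.0 / fs)):.3g} s exceeds {UNIFORMITY_TOL} s"
        )
    return fs


@dataclass
class AccelTrace:
    """One ankle sensor's 3-axis acceleration series (g-units).

    In the *sensor* frame the channels are the raw device axes (x up the
    shank).  After :func:`harmonize_axes` the frame is *anatomical* and the
    channels are exposed as :attr:`vertical`, :attr:`anterior`,
    :attr:`lateral`.
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    fs: float
    side: str
    frame: str = "sensor"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        _check_side(self.side)
        if self.frame not in ("sensor", "anatomical"):
            raise ParameterError(f"unknown frame {self.frame!r}")
        n = len(self.t)
        if n < 2:
            raise FormatError("accelerometer trace needs at least 2 samples")
        if not (len(self.ax) == len(self.ay) == len(self.az) == n):
            raise FormatError("all acceleration channels must share one length")
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        if np.any(np.abs(np.diff(self.t) - 1.0 / self.fs) > UNIFORMITY_TOL):
            raise FormatError("time stamps are not uniform at 1/fs")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def _anatomical(self, name: str) -> np.ndarray:
        if self.frame != "anatomical":
            raise ParameterError(
                f"{name} channel requires the anatomical frame; call harmonize_axes first"
            )
        return {"vertical": self.ax, "anterior": self.ay, "lateral": self.az}[name]

    @property
    def vertical(self) -> np.ndarray:
        return self._anatomical("vertical")

    @property
    def anterior(self) -> np.ndarray:
        return self._anatomical("anterior")

    @property
    def lateral(self) -> np.ndarray:
        return self._anatomical("lateral")


@dataclass
class BiomechTrace:
    """Per-limb force-plate / inverse-dynamics series.

    ``vgrf``/``agrf`` in newtons, ``kfm``/``kam`` in newton-metres (raw,
    i.e. not yet normalised by body mass).
    """

    t: np.ndarray
    vgrf: np.ndarray
    agrf: np.ndarray
    kfm: np.ndarray
    kam: np.ndarray
    fs: float
    side: str

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("vgrf", "agrf", "kfm", "kam"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        _check_side(self.side)
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        n = len(self.t)
        if n < 2:
            raise FormatError("biomechanical trace needs at least 2 samples")
        for name in ("vgrf", "agrf", "kfm", "kam"):
            if len(getattr(self, name)) != n:
                raise FormatError("all biomechanical channels must share one length")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class SubjectMeta:
    """Anthropometrics and surgical side for one participant."""

    subject_id: str
    height: float  # m
    mass: float  # kg
    surgical_side: str
    age: Optional[float] = None
    sex: Optional[str] = None

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ParameterError("height must be positive (metres)")
        if self.mass <= 0:
            raise ParameterError("mass must be positive (kg)")
        _check_side(self.surgical_side)

    @property
    def nonsurgical_side(self) -> str:
        return "right" if self.surgical_side == "left" else "left"


def _read_csv(path, columns) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required columns {missing}")
    return df


def read_accel_csv(path, side: str) -> AccelTrace:
    """Read a `time,ax,ay,az` CSV into a sensor-frame :class:`AccelTrace`.

    The sampling rate is inferred from the median timestep and the grid is
    required to be uniform to within ``UNIFORMITY_TOL``.
    """
    df = _read_csv(path, ACCEL_COLUMNS)
    t = df["time"].to_numpy(dtype=float)
    fs = _infer_fs(t)
    return AccelTrace(
        t=t,
        ax=df["ax"].to_numpy(dtype=float),
        ay=df["ay"].to_numpy(dtype=float),
        az=df["az"].to_numpy(dtype=float),
        fs=fs,
        side=_check_side(side),
        frame="sensor",
    )


def write_accel_csv(trace: AccelTrace, path, header_comment: Optional[str] = None) -> None:
    path = Path(path)
    df = pd.DataFrame({"time": trace.t, "ax": trace.ax, "ay": trace.ay, "az": trace.az})
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def read_biomech_csv(path, side: str) -> BiomechTrace:
    """Read a `time,vgrf,agrf,kfm,kam` CSV into a :class:`BiomechTrace`.

    Negative vGRF samples are accepted with a warning (force-plate baseline
    noise), matching a tolerant-ingest policy.
    """
    df = _read_csv(path, BIOMECH_COLUMNS)
    t = df["time"].to_numpy(dtype=float)
    fs = _infer_fs(t)
    vgrf = df["vgrf"].to_numpy(dtype=float)
    if np.any(vgrf < 0):
        warnings.warn(
            f"{Path(path).name}: vGRF contains negative samples (baseline noise?)",
            stacklevel=2,
        )
    return BiomechTrace(
        t=t,
        vgrf=vgrf,
        agrf=df["agrf"].to_numpy(dtype=float),
        kfm=df["kfm"].to_numpy(dtype=float),
        kam=df["kam"].to_numpy(dtype=float),
        fs=fs,
        side=_check_side(side),
    )


def write_biomech_csv(trace: BiomechTrace, path, header_comment: Optional[str] = None) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "time": trace.t,
            "vgrf": trace.vgrf,
            "agrf": trace.agrf,
            "kfm": trace.kfm,
            "kam": trace.kam,
        }
    )
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def harmonize_axes(trace: AccelTrace, mirror_side: str = MIRROR_SIDE) -> AccelTrace:
    """Map a sensor-frame trace into the anatomical frame.

    vertical = sensor x (up the shank), anterior = sensor y, lateral =
    sensor z with the sign flipped on ``mirror_side`` so that +lateral points
    away from the midline on both limbs.  Per-sample vector magnitude is
    preserved exactly.  Calling on an already-anatomical trace is a no-op
    with a warning (idempotent).
    """
    if trace.frame == "anatomical":
        warnings.warn("trace is already in the anatomical frame; returning as-is", stacklevel=2)
        return trace
    flip = -1.0 if trace.side == _check_side(mirror_side) else 1.0
    return replace(trace, az=flip * trace.az, frame="anatomical")


def read_subjects_csv(path) -> list[SubjectMeta]:
    """Read `subjects.csv` (id,height_m,mass_kg,surgical_side[,age,sex])."""
    df = _read_csv(path, ["id", "height_m", "mass_kg", "surgical_side"])
    subjects = []
    for _, row in df.iterrows():
        subjects.append(
            SubjectMeta(
                subject_id=str(row["id"]),
                height=float(row["height_m"]),
                mass=float(row["mass_kg"]),
                surgical_side=str(row["surgical_side"]),
                age=float(row["age"]) if "age" in df.columns and pd.notna(row.get("age")) else None,
                sex=str(row["sex"]) if "sex" in df.columns and pd.notna(row.get("sex")) else None,
            )
        )
    return subjects


def write_subjects_csv(subjects: list[SubjectMeta], path) -> None:
    rows = [
        {
            "id": s.subject_id,
            "height_m": s.height,
            "mass_kg": s.mass,
            "surgical_side": s.surgical_side,
            "age": s.age,
            "sex": s.sex,
        }
        for s in subjects
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def validate_io(directory) -> list[str]:
    """Check a data directory for well-formed trace and metadata files.

    Returns a list of human-readable problem strings (empty = all good).
    Used by the ``validate-io`` CLI command.
    """
    directory = Path(directory)
    problems: list[str] = []
    subjects_path = directory / "subjects.csv"
    if not subjects_path.exists():
        problems.append("subjects.csv not found")
        return problems
    try:
        subjects = read_subjects_csv(subjects_path)
    except (FormatError, ParameterError) as exc:
        problems.append(f"subjects.csv: {exc}")
        return problems
    for s in subjects:
        for side in SIDES:
            for kind, reader in (("accel", read_accel_csv), ("biomech", read_biomech_csv)):
                fname = directory / f"{s.subject_id}_{side}_{kind}.csv"
                if not fname.exists():
                    problems.append(f"missing {fname.name}")
                    continue
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        reader(fname, side)
                except (FormatError, ParameterError) as exc:
                    problems.append(f"{fname.name}: {exc}")
    return problems
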