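"""End-to-end orchestration: simulate → detect → extract → summarize → model.

A :class:`RunConfig` gathers every tunable parameter; :func:`run_all`
executes the stages in order, writing each stage's CSV plus a manifest that
echoes the configuration and its hash, so a rerun with the same config
reproduces identical outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomech_features import extract_biomech_trial
from .exceptions import GaitKitError, ParameterError
from .gait_events import (
    build_stride_cycles,
    detect_heel_strikes_accel,
    detect_steps_grf,
    validate_events,
)
from .inertial_features import extract_inertial_trial
from .models import run_model_suite
from .signal_io import (
    SubjectMeta,
    harmonize_axes,
    read_accel_csv,
    read_biomech_csv,
    read_subjects_csv,
)
from .synthetic_gait import (
    GaitSimParams,
    SyntheticTrial,
    simulate_cohort,
    simulate_trial,
    write_cohort,
    write_trial,
)
from .trial_summary import flag_outlier_subjects, summarize_trial


@dataclass
class RunConfig:
    """All pipeline parameters; defaults match the module-level defaults."""

    out_dir: str = "gaitkit_run"
    data_dir: Optional[str] = None  # None -> simulate a cohort
    # simulation (used when data_dir is None)
    n_subjects: int = 18
    n_strides: int = 30
    asymmetry_sd: float = 0.08
    noise_sd: float = 0.02
    write_traces: bool = False
    # event detection
    threshold_frac: float = 0.20
    min_interval: float = 0.4
    min_prominence: float = 0.5
    event_tol: float = 0.05  # s, accel-vs-GRF validation tolerance
    # feature extraction
    hs_window: float = 0.10
    stance_frac: float = 0.60
    tilt_cutoff: float = 3.0
    initial_frac: float = 0.10
    # summarisation and modelling
    si_mode: str = "stride"
    k_folds: int = 10
    p_enter: float = 0.05
    cv: bool = True
    mad_cutoff: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.threshold_frac < 1:
            raise ParameterError("threshold_frac must lie in (0, 1)")
        if not 0 < self.stance_frac < 1:
            raise ParameterError("stance_frac must lie in (0, 1)")
        if self.min_interval <= 0 or self.min_prominence <= 0 or self.hs_window <= 0:
            raise ParameterError("detection parameters must be positive")
        if self.k_folds < 2:
            raise ParameterError("k_folds must be at least 2")
        if self.n_subjects < 2:
            raise ParameterError("n_subjects must be at least 2")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        """Hash of the analysis parameters (the output location is excluded,
        so reruns into different directories compare equal)."""
        d = asdict(self)
        d.pop("out_dir")
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def process_trial(
    subject: SubjectMeta,
    accel: dict,
    biomech: dict,
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detect events and extract per-stride features for one trial.

    ``accel``/``biomech`` map side -> sensor-frame trace.  Returns
    (per-stride feature table with both limbs, event QC table).
    """
    stride_tables = []
    qc_rows = []
    for side in ("left", "right"):
        anat = harmonize_axes(accel[side])
        hs = detect_heel_strikes_accel(
            anat, min_interval=config.min_interval, min_prominence=config.min_prominence
        )
        grf_starts = detect_steps_grf(
            biomech[side], threshold_frac=config.threshold_frac, min_gap=config.min_interval
        )
        match = validate_events(hs, grf_starts, tol=config.event_tol)
        qc_rows.append(
            {
                "subject_id": subject.subject_id,
                "side": side,
                "n_hs_accel": len(hs),
                "n_starts_grf": len(grf_starts),
                "n_matched": match.n_matched,
                "n_missed": match.n_missed,
                "n_spurious": match.n_spurious,
                "mean_abs_dt": match.mean_abs_dt,
            }
        )
        cycles = build_stride_cycles(hs, anat.fs, stance_frac=config.stance_frac, side=side)
        if not cycles:
            continue
        inert = extract_inertial_trial(
            cycles,
            anat,
            subject=subject,
            hs_window=config.hs_window,
            initial_frac=config.initial_frac,
            stance_frac=config.stance_frac,
            tilt_cutoff=config.tilt_cutoff,
        )
        bio = extract_biomech_trial(
            cycles, biomech[side], subject=subject, threshold_frac=config.threshold_frac
        )
        merged = inert.merge(
            bio.drop(columns=["hs_time", "next_hs_time"]), on=["side", "stride"]
        )
        stride_tables.append(merged)
    strides = pd.concat(stride_tables, ignore_index=True) if stride_tables else pd.DataFrame()
    return strides, pd.DataFrame(qc_rows)


def _load_trial(data_dir: Path, subject: SubjectMeta):
    accel = {s: read_accel_csv(data_dir / f"{subject.subject_id}_{s}_accel.csv", s) for s in ("left", "right")}
    biomech = {s: read_biomech_csv(data_dir / f"{subject.subject_id}_{s}_biomech.csv", s) for s in ("left", "right")}
    return accel, biomech


@dataclass
class RunResult:
    """Outputs of one pipeline run (also written to ``out_dir``)."""

    config: RunConfig
    summary: pd.DataFrame
    strides: pd.DataFrame
    events_qc: pd.DataFrame
    suites: dict  # mode -> ModelSuiteResult
    out_dir: Path


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# gaitkit config={config_hash}\n")
        df.to_csv(fh, index=False)


def run_all(config: RunConfig) -> RunResult:
    """Execute the full pipeline under one configuration.

    Stages: (1) load or simulate the cohort, (2) event detection and QC,
    (3) per-stride feature extraction, (4) trial summarisation and outlier
    flagging, (5) model suites for both the average and symmetry modes.
    Every stage output lands in ``config.out_dir`` tagged with the config
    hash; identical configs reproduce identical bytes.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash

    stage = "load"
    try:
        if config.data_dir is None:
            stage = "simulate"
            cohort = simulate_cohort(
                n_subjects=config.n_subjects,
                seed=config.seed,
                n_strides=config.n_strides,
                include_traces=True,
                asymmetry_sd=config.asymmetry_sd,
                base_params=GaitSimParams(noise_sd=config.noise_sd),
            )
            subjects = cohort.subjects
            trials = {s.subject_id: t for s, t in zip(subjects, cohort.trials)}
            if config.write_traces:
                write_cohort(cohort, out / "traces")
        else:
            subjects = read_subjects_csv(Path(config.data_dir) / "subjects.csv")
            trials = None

        stride_tables, qc_tables, summary_rows = [], [], []
        for subject in subjects:
            stage = f"process subject {subject.subject_id}"
            if trials is not None:
                trial = trials[subject.subject_id]
                accel = {s: trial.accel(s) for s in ("left", "right")}
                biomech = {s: trial.biomech(s) for s in ("left", "right")}
            else:
                accel, biomech = _load_trial(Path(config.data_dir), subject)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                strides, qc = process_trial(subject, accel, biomech, config)
                if strides.empty:
                    raise GaitKitError(f"no strides extracted for {subject.subject_id}")
                summary_rows.append(summarize_trial(strides, subject, si_mode=config.si_mode))
            strides.insert(0, "subject_id", subject.subject_id)
            stride_tables.append(strides)
            qc_tables.append(qc)

        stage = "summarize"
        strides_df = pd.concat(stride_tables, ignore_index=True)
        qc_df = pd.concat(qc_tables, ignore_index=True)
        summary = pd.DataFrame(summary_rows).reset_index(drop=True)
        summary["outlier_flag"] = flag_outlier_subjects(summary, cutoff=config.mad_cutoff).values

        stage = "model"
        suites = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for mode in ("average", "symmetry"):
                suites[mode] = run_model_suite(
                    summary,
                    mode=mode,
                    seed=config.seed,
                    k_folds=config.k_folds,
                    cv=config.cv,
                    p_enter=config.p_enter,
                    mad_cutoff=config.mad_cutoff,
                )
    except GaitKitError as exc:
        raise GaitKitError(f"pipeline failed at stage '{stage}': {exc}") from exc

    stage = "write"
    _write_csv(qc_df, out / "events_qc.csv", h)
    _write_csv(strides_df, out / "strides.csv", h)
    _write_csv(summary, out / "summary.csv", h)
    reports_dir = out / "reports"
    reports_dir.mkdir(exist_ok=True)
    report_lines = []
    for mode, suite in suites.items():
        for branch, resmap in (
            ("all", suite.all_subjects),
            ("excl", suite.excluding_outliers or {}),
        ):
            for tgt, res in resmap.items():
                _write_csv(res.steps, reports_dir / f"{mode}_{tgt}_{branch}.csv", h)
                report_lines.append(res.summary())
                report_lines.append("")
        suite.correlations.formatted.to_csv(reports_dir / f"{mode}_correlations.csv")

    manifest = {
        "gaitkit_version": __version__,
        "config": asdict(config),
        "config_hash": h,
        "n_subjects": len(subjects),
        "outliers": suites["average"].outlier_ids,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    (out / "report.txt").write_text("\n".join(report_lines))

    return RunResult(
        config=config,
        summary=summary,
        strides=strides_df,
        events_qc=qc_df,
        suites=suites,
        out_dir=out,
    )


def make_fixtures(out_dir, seed: int = 0) -> Path:
    """Write a 3-subject mini-cohort (10 complete strides per side) with
    truth sidecars; used by the test suite and as a worked example."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subjects = [
        SubjectMeta("F01", 1.71, 87.1, "left", age=66.0),
        SubjectMeta("F02", 1.65, 72.0, "right", age=63.0),
        SubjectMeta("F03", 1.80, 95.0, "left", age=70.0),
    ]
    asyms = [1.0, 0.85, 1.1]
    trials = []
    for i, (subject, asym) in enumerate(zip(subjects, asyms)):
        params = GaitSimParams(
            n_strides=11, asymmetry=asym, noise_sd=0.02, seed=seed + i
        )
        trial = simulate_trial(params, subject)
        write_trial(trial, out_dir)
        trials.append(trial)
    from .signal_io import write_subjects_csv

    write_subjects_csv(subjects, out_dir / "subjects.csv")
    return out_dir
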