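import numpy as np
import pytest

from gaitkit import GaitSimParams, SubjectMeta, simulate_trial
from gaitkit.pipeline import make_fixtures


@pytest.fixture(scope="session")
def subject():
    return SubjectMeta("T01", height=1.71, mass=87.1, surgical_side="left", age=66.0)


@pytest.fixture(scope="session")
def noiseless_trial(subject):
    """20-stride perfectly clean trial: detection and extraction must be exact."""
    params = GaitSimParams(seed=7, n_strides=20, noise_sd=0.0, asymmetry=1.0)
    return simulate_trial(params, subject)


@pytest.fixture(scope="session")
def asymmetric_trial(subject):
    """Clean trial with a 0.8 surgical/non-surgical amplitude ratio."""
    params = GaitSimParams(seed=7, n_strides=20, noise_sd=0.0, asymmetry=0.8)
    return simulate_trial(params, subject)


@pytest.fixture(scope="session")
def noisy_trial(subject):
    """60-stride trial with 0.05 g sensor noise (the detection stress case)."""
    params = GaitSimParams(seed=11, n_strides=60, noise_sd=0.05)
    return simulate_trial(params, subject)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """3-subject mini-cohort written to disk with truth sidecars."""
    out = tmp_path_factory.mktemp("mini_cohort")
    make_fixtures(out, seed=0)
    return out


def truth_strides(trial, side):
    """Complete-stride truth rows for one side (drops the trailing HS row)."""
    t = trial.truth
    rows = t[(t["side"] == side) & t["st"].notna()]
    return rows.reset_index(drop=True)
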