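import numpy as np
import pytest

from ppgbp import synthetic as syn
from ppgbp.preprocess import WindowingConfig
from ppgbp import datasets as ds


@pytest.fixture(scope="session")
def drift_free_profile():
    """Noise- and drift-free subject: exact ABP extrema by construction."""
    return syn.SyntheticSubjectProfile(
        subject_id="exact", base_hr=60.0, hr_jitter_sd=0.0,
        base_sbp=120.0, base_dbp=60.0, bp_drift_amplitude=0.0,
        noise_sd=0.0, record_duration=60.0, seed=7)


@pytest.fixture(scope="session")
def drift_free_record(drift_free_profile):
    return syn.generate_subject_record(drift_free_profile, fs=125.0)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = syn.CohortConfig(
        n_subjects=8, seed=42,
        subject_size_distribution={"median_s": 150.0, "sigma_log": 0.3},
        min_duration_s=100.0, max_duration_s=300.0, noise_sd=0.02)
    return syn.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_pool(small_cohort):
    return ds.build_pool(small_cohort.records,
                         windowing=WindowingConfig("const_time", 7))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
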