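"""Shared fixtures: a small synthetic cohort and its prepared study data."""

import pytest

import nestcc as ncc


@pytest.fixture(scope="session")
def small_tables():
    """Synthetic cohort of 3,000 patients (fixed seed), raw tables + truth."""
    cfg = ncc.GeneratorConfig(n_patients=3000, seed=11)
    return ncc.generate_population(cfg)


@pytest.fixture(scope="session")
def study_config():
    return ncc.StudyConfig(seed=11)


@pytest.fixture(scope="session")
def study_data(small_tables, study_config):
    """Prepared pipeline state (screen -> match -> exposure -> covariates)."""
    patients, prescriptions, diagnoses, _ = small_tables
    return ncc.prepare_study(patients, prescriptions, diagnoses, study_config)


@pytest.fixture(scope="session")
def mid_tables():
    """A 12,000-patient cohort: enough cases for stable regression fits."""
    cfg = ncc.GeneratorConfig(n_patients=12000, seed=23)
    return ncc.generate_population(cfg)


@pytest.fixture(scope="session")
def mid_study_data(mid_tables):
    patients, prescriptions, diagnoses, _ = mid_tables
    return ncc.prepare_study(patients, prescriptions, diagnoses, ncc.StudyConfig(seed=23))
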