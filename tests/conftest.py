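"""Shared fixtures: small synthetic cohorts, generated once per session."""

import numpy as np
import pytest

import seizurekit as sk


@pytest.fixture(scope="session")
def tiny_config():
    """Three-patient neonatal-like cohort with short recordings."""
    return sk.neonatal_config(n_patients=3, duration_s=240, seed=11,
                              seizure_duration_s=(20.0, 40.0),
                              seizure_rate=1.0)


@pytest.fixture(scope="session")
def tiny_tensors(tiny_config):
    """Feature tensors of the tiny cohort (preprocessed, epoched)."""
    return sk.extract_cohort_tensors(tiny_config)


@pytest.fixture(scope="session")
def tiny_recording(tiny_config):
    return sk.generate_recording(tiny_config, patient_index=0, record_index=0)


@pytest.fixture()
def rng():
    # fresh generator per test: results never depend on execution order
    return np.random.default_rng(1234)
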