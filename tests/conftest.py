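import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sadmad.design import PKModelParams, default_study_design

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design():
    return default_study_design()


@pytest.fixture(scope="session")
def noiseless_params():
    return PKModelParams(CL=0.2, V=7.0, ka=0.5, F_abs=0.9).noiseless()


@pytest.fixture(scope="session")
def trial_dataset(design):
    """One full simulated trial shared across tests (seed fixed)."""
    from sadmad.simulate import simulate_trial

    return simulate_trial(design, seed=1)


@pytest.fixture(scope="session")
def nca_table(trial_dataset):
    from sadmad.nca import nca_subject_table

    return nca_subject_table(trial_dataset.pk_conc, trial_dataset.dosing, trial_dataset.subjects)
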