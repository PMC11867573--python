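import numpy as np
import pytest
from hypothesis import settings

from contourvar import PhantomParams, generate_base_patient, generate_cohort, preset_models

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params() -> PhantomParams:
    return PhantomParams()


@pytest.fixture(scope="session")
def bladder_phantom(default_params):
    """Ground-truth bladder mask of one default synthetic patient."""
    return generate_base_patient(default_params, patient_seed=0)["bladder"]


@pytest.fixture(scope="session")
def clean_cohort(tmp_path_factory):
    """3-patient cohort with zero perturbation: every cell equals ground truth."""
    out = tmp_path_factory.mktemp("clean_cohort")
    observers, sequences = preset_models("clean")
    return generate_cohort(3, PhantomParams(), observers, sequences, out, seed=7)


@pytest.fixture(scope="session")
def noisy_cohort(tmp_path_factory):
    """8-patient paper_like cohort shared across pipeline tests."""
    out = tmp_path_factory.mktemp("noisy_cohort")
    observers, sequences = preset_models("paper_like")
    return generate_cohort(8, PhantomParams(), observers, sequences, out, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
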