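import numpy as np
import pytest

from dvjmech import synthetic as syn
from dvjmech.metrics import analyze_trial
from dvjmech.model import SubjectSpec, build_body_model


@pytest.fixture(scope="session")
def subject():
    return SubjectSpec(**syn.DEFAULT_SUBJECT)


@pytest.fixture(scope="session")
def model(subject):
    return build_body_model(subject)


@pytest.fixture(scope="session")
def static_clean(subject, model):
    return syn.generate_static_trial(subject, marker_noise_sd=0.0,
                                     force_noise_sd=0.0, model=model)


@pytest.fixture(scope="session")
def baseline_clean(subject, model):
    params = syn.preset("baseline", marker_noise_sd=0.0, force_noise_sd=0.0)
    return syn.generate_dvj_trial(subject, params, model)


@pytest.fixture(scope="session")
def damaged_clean(subject, model):
    params = syn.preset("damaged48h", marker_noise_sd=0.0, force_noise_sd=0.0)
    return syn.generate_dvj_trial(subject, params, model)


@pytest.fixture(scope="session")
def baseline_analysis(baseline_clean, static_clean):
    return analyze_trial(baseline_clean, static_clean)


@pytest.fixture(scope="session")
def damaged_analysis(damaged_clean, static_clean):
    return analyze_trial(damaged_clean, static_clean)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
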