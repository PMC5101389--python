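import warnings

import pytest
from hypothesis import settings

import chromdoe as cd

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

# the exhausted-deflation RuntimeWarning from deep PLS component counts is
# expected on (near-)noiseless responses
warnings.filterwarnings("ignore", message=".*invalid value encountered.*")


@pytest.fixture(scope="session")
def factors():
    return cd.HILIC_FACTORS


@pytest.fixture(scope="session")
def design(factors):
    return cd.build_ccd(factors, n_center=6)


@pytest.fixture(scope="session")
def truth():
    return cd.default_ground_truth()


@pytest.fixture(scope="session")
def noiseless_responses(truth, design):
    return cd.generate_study(truth, design, noise=False)


@pytest.fixture(scope="session")
def noiseless_models(design, noiseless_responses):
    return cd.fit_response_models(
        design, noiseless_responses.drop(columns="run_id"), with_ci=True
    )
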