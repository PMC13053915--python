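import numpy as np
import pytest

from nmrdyn.exchange import CpmgSchedule, ExchangeParams
from nmrdyn.synth import DEFAULT_SCHEDULE, StudyDesign, emit_study, make_ground_truth


@pytest.fixture(scope="session")
def schedule() -> CpmgSchedule:
    return CpmgSchedule()


@pytest.fixture(scope="session")
def fast_params() -> ExchangeParams:
    return ExchangeParams(p_b=0.05, k_ex=2000.0, delta_omega=600.0, r2_a=10.0)


@pytest.fixture(scope="session")
def ground_truth():
    return make_ground_truth(StudyDesign(), DEFAULT_SCHEDULE, rng_seed=1)


@pytest.fixture(scope="session")
def study_zero_noise(ground_truth, tmp_path_factory):
    out = tmp_path_factory.mktemp("study_zero")
    return emit_study(ground_truth, out, rng_seed=1, noise=0.0)


@pytest.fixture(scope="session")
def study_default_noise(ground_truth, tmp_path_factory):
    out = tmp_path_factory.mktemp("study_noisy")
    return emit_study(ground_truth, out, rng_seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
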