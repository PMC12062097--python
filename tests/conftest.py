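import numpy as np
import pytest

from aggdiff.landscape import SingleClumpEnvironment
from aggdiff.steady_state import ModelParams


@pytest.fixture
def default_params() -> ModelParams:
    """The paper-style defaults: gamma=2, sigma=0.1, p=1, fourth-order family."""
    return ModelParams(gamma=2.0, sigma=0.1, p=1.0)


@pytest.fixture
def laplace_params() -> ModelParams:
    return ModelParams(gamma=2.0, m=10.0, p=1.0, model_family="laplace")


@pytest.fixture
def clump_env() -> SingleClumpEnvironment:
    return SingleClumpEnvironment(n=1, amplitude=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_exact_branch_candidate(rng, params_cls=ModelParams):
    """Draw (params, env, r) with r <= 1/n so the candidate family is exact."""
    from aggdiff.errors import NoCandidateError, ResonanceError
    from aggdiff.steady_state import build_candidate

    while True:
        gamma = rng.uniform(1.2, 5.0)
        sigma = rng.uniform(0.05, 0.3)
        n = int(rng.integers(1, 17))
        a_n = rng.uniform(0.0, 10.0)
        params = params_cls(gamma=gamma, sigma=sigma, p=1.0)
        env = SingleClumpEnvironment(n=n, amplitude=a_n)
        r = rng.uniform(0.02, 1.0 / n)
        try:
            return params, env, build_candidate(params, env, r)
        except (NoCandidateError, ResonanceError):
            continue
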