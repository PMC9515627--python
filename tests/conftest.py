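import numpy as np
import pytest

from plever import Model1Params, Model2Params


@pytest.fixture
def typical_intake_params() -> Model1Params:
    """Protein at 15% of an 8700 kJ total with equal 500 kJ SDs."""
    return Model1Params(mu_U=1305.0, mu_V=7395.0, sigma_U=500.0, sigma_V=500.0, rho_UV=0.3)


@pytest.fixture
def symmetric_params() -> Model1Params:
    return Model1Params(mu_U=4350.0, mu_V=4350.0, sigma_U=500.0, sigma_V=500.0, rho_UV=0.0)


@pytest.fixture
def pl_params() -> Model2Params:
    """Generative parameters: 20% mean protein share, SD 0.05, moderate leverage."""
    return Model2Params.from_share_moments(0.2, 0.05, -0.5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220756)


def ratio_samples(params: Model1Params, n: int, seed: int) -> np.ndarray:
    """Monte-Carlo draws of W = U/(U+V) from the bivariate normal intake model."""
    gen = np.random.default_rng(seed)
    cov = [
        [params.sigma_U**2, params.sigma_UV],
        [params.sigma_UV, params.sigma_V**2],
    ]
    uv = gen.multivariate_normal([params.mu_U, params.mu_V], cov, size=n)
    return uv[:, 0] / uv.sum(axis=1)
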