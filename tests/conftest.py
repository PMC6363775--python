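import pytest

from pggdyn import ModelParams


@pytest.fixture
def fig1_base() -> ModelParams:
    """Small-capacity parameter set used by the phase-diagram examples."""
    return ModelParams(
        alpha_C=1.0, alpha_D=1.0, delta_C=0.05, delta_D=0.05,
        kappa=0.1, K=100.0, beta=1.0, sigma=1.0,
    ).with_(n=5)


@pytest.fixture
def large_K_base() -> ModelParams:
    """K=1000 parameter set shared by the stochastic and compartment scenarios."""
    return ModelParams(
        alpha_C=1.0, alpha_D=1.0, delta_C=0.1, delta_D=0.1,
        kappa=0.5, K=1000.0, beta=2.0, sigma=3.0,
    ).with_(n=10)


@pytest.fixture
def fitted_fbs5() -> ModelParams:
    """Parameter set from the fitted 5% FBS medians (beta=3.67, sigma=1.87)."""
    return ModelParams(
        alpha_C=1.0, alpha_D=1.0, delta_C=0.1, delta_D=0.1,
        kappa=0.25, K=1000.0, beta=3.67, sigma=1.87,
    ).with_(n=22)
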