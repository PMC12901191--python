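import pytest

from licoquant.simulate import SimConfig


@pytest.fixture
def noiseless_config() -> SimConfig:
    """All stochastic terms off; response is exactly the configured line."""
    return SimConfig(
        cv_intra=0.0, cv_inter_day=0.0, cv_is=0.0, cv_ion_ratio=0.0,
        rt_jitter_sd=0.0, recovery_true=1.0, matrix_factor_true=1.0,
        matrix_factor_is_true=1.0, pk_bsv_cv=0.0,
    )


@pytest.fixture
def default_config() -> SimConfig:
    return SimConfig()
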