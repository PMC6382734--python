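import pytest

from nskf import ModelParams, build_schedule, default_agent, generate_session


@pytest.fixture(scope="session")
def mc_params() -> ModelParams:
    """Fitted multisensory-condition parameters."""
    return ModelParams(base_meas_var=0.0010, delta_meas_var=1.7e-4)


@pytest.fixture(scope="session")
def uc_params() -> ModelParams:
    """Fitted unisensory-condition parameters."""
    return ModelParams(base_meas_var=0.0015, delta_meas_var=3.7e-4)


@pytest.fixture(scope="session")
def incremental_schedule():
    """The experiment's own paradigm: 135 baseline + 1 ms/trial ramp to 135 ms."""
    return build_schedule("incremental")


@pytest.fixture
def mc_session():
    """One reproducible synthetic MC session on the incremental schedule."""
    return generate_session(default_agent("MC", seed=42), participant="p01")
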