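import pytest
from hypothesis import HealthCheck, settings

from cutigas import FvCBParams
from cutigas.synthetic import ProtocolSpec, StomatalModel, generate_curve

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_params() -> FvCBParams:
    """Forward-model defaults: vcmax 50, j 100, rd 1.5, 25 degC kinetics."""
    return FvCBParams()


@pytest.fixture(scope="session")
def rich_params() -> FvCBParams:
    """A leaf whose SS curve samples all three limitations."""
    return FvCBParams(vcmax=100.0, j=150.0, tpu=11.0, rd=1.5)


@pytest.fixture(scope="session")
def clean_ss_frame(rich_params):
    """Noise-free SS curve, static stomata, no cuticular conductance."""
    return generate_curve(
        ProtocolSpec.steady_state(),
        params=rich_params,
        stomata=StomatalModel.static(0.25, 0.0),
    )
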