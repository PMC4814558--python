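import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from thfkin.model import (
    ConstantFlux,
    ModelConfig,
    PathwayModel,
    Reaction,
    SaturatingIrrev,
    Species,
    build_reference_model,
)
from thfkin.simulate import steady_state

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_config():
    return ModelConfig.default()


@pytest.fixture(scope="session")
def reference_model(default_config):
    return build_reference_model(default_config)


@pytest.fixture(scope="session")
def wt_ss(reference_model):
    return steady_state(reference_model)


def make_monod_toy(v0: float = 2e-7, vmax: float = 4e-7, km: float = 1e-6,
                   x0: float = 0.0) -> PathwayModel:
    """One-species toy: constant source v0, Michaelis-Menten drain.

    Closed-form steady state [X]ss = km*v0/(vmax - v0) for v0 < vmax;
    elasticity of [X]ss to v0 is vmax/(vmax - v0).
    """
    return PathwayModel(
        species=[Species("X", "X", x0)],
        reactions=[
            Reaction("src", {}, {"X": 1}, ConstantFlux(v0)),
            Reaction("drain", {"X": 1}, {}, SaturatingIrrev(vmax, km)),
        ],
    )


@pytest.fixture
def monod_toy():
    return make_monod_toy()


V_NET = 1.66e-7
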