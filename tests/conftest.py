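import numpy as np
import pytest

from pistar import (
    EnvironmentProtocol,
    GeneratorConfig,
    ModelVariant,
    default_parameters,
    generate,
    initial_steady_state,
    simulate,
    to_fold_change,
)
from pistar.synth import LONG_TIMES


@pytest.fixture(scope="session")
def piom():
    return ModelVariant("PIOM")


@pytest.fixture(scope="session")
def pstr_rp():
    return ModelVariant("PSTR", rp=True)


@pytest.fixture(scope="session")
def piom_params(piom):
    return default_parameters(piom)


@pytest.fixture(scope="session")
def piom_steady_state(piom, piom_params):
    return initial_steady_state(piom_params, piom)


@pytest.fixture(scope="session")
def long_starvation_data(piom, piom_params):
    """Replicate table simulated from the base model at known parameters."""
    times = np.asarray(LONG_TIMES, dtype=float)
    protocol = EnvironmentProtocol.starvation(times[-1])
    traj = simulate(piom_params, piom, protocol, times)
    curves = to_fold_change(traj)
    cfg = GeneratorConfig(scenario="long_starvation", cv=0.2, seed=7)
    return generate(cfg, curves=curves)
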