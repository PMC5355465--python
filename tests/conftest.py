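import numpy as np
import pytest
from hypothesis import settings

from iggkin.kinetics import DEFAULT_PARAMETERS, MetabolicParameters

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def params() -> MetabolicParameters:
    """Population-average parameter set used throughout the tests."""
    return DEFAULT_PARAMETERS


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


def random_valid_parameters(rng: np.random.Generator) -> MetabolicParameters:
    """Draw a parameter set satisfying positivity and net-elimination
    invariants by construction: pick k31 and the recycling fraction
    Vmax/KM strictly below it."""
    k12 = rng.uniform(0.05, 1.0)
    k21 = rng.uniform(0.05, 1.0)
    k31 = rng.uniform(0.05, 0.5)
    frac = rng.uniform(0.1, 0.9)  # Vmax/KM as a fraction of k31
    KM = rng.uniform(50.0, 1000.0)
    return MetabolicParameters(k12=k12, k21=k21, k31=k31,
                               Vmax=frac * k31 * KM, KM=KM)
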