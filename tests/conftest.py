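import numpy as np
import pytest

from radiopbpk.model import ModelParameters
from radiopbpk.physiology import build_compartments, default_physiology
from radiopbpk.synthetic import (
    NoiseModel,
    builtin_design,
    default_true_parameters,
    generate,
)

A0 = 7.4e9  # administered activity [Bq]


@pytest.fixture(scope="session")
def compartments():
    return build_compartments(default_physiology())


@pytest.fixture(scope="session")
def truth():
    return default_true_parameters()


@pytest.fixture(scope="session")
def noise_free_dataset(compartments, truth):
    """Synthetic patient-1-style dataset generated without noise."""
    return generate(
        truth, compartments, A0, builtin_design(1), NoiseModel(kind="none")
    )


def random_parameters(rng: np.random.Generator) -> ModelParameters:
    """Log-uniform random kinetic parameters spanning plausible ranges."""
    p = {t: float(np.exp(rng.uniform(np.log(0.1), np.log(10)))) for t in
         ("Lu", "K", "L", "BR", "RB")}
    cl = {t: float(np.exp(rng.uniform(np.log(0.1), np.log(100)))) for t in ("K", "L")}
    return ModelParameters(partition=p, clearance=cl)
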