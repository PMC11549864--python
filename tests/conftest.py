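import numpy as np
import pytest

from ribload import simdata
from ribload.model import ModelSpec, build_model, train


@pytest.fixture(scope="session")
def default_params() -> simdata.SimParams:
    return simdata.SimParams(seed=0)


@pytest.fixture(scope="session")
def small_simulated_library(default_params) -> simdata.ReporterLibrary:
    """4,000 simulated random reporters with an 80/20 train/test split."""
    lib = simdata.generate_random_library(4000, seed=11)
    lib = simdata.simulate_library(lib, simdata.with_params(default_params, seed=11))
    return simdata.assign_random_split(lib, 800, seed=11)


@pytest.fixture(scope="session")
def small_trained_model(small_simulated_library):
    """Default CNN trained briefly on the small library (shared across tests)."""
    spec = ModelSpec()
    net = build_model(spec, seed=7)
    return train(net, small_simulated_library, epochs=2, seed=7, spec=spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_seqs(rng: np.random.Generator, n: int, length: int = 50) -> list[str]:
    bases = np.array(list("ACGT"))
    return ["".join(row) for row in bases[rng.integers(0, 4, size=(n, length))]]
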