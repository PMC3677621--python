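import numpy as np
import pytest

from seirvax import Parameters, reference_parameters


@pytest.fixture(scope="session")
def ref_params() -> Parameters:
    """The built-in benchmark parameter set (R0 ~ 10, stable endemic point)."""
    return reference_parameters()


@pytest.fixture(scope="session")
def ref_params_absolute() -> Parameters:
    """Benchmark rates extended with d, sigma, a for the absolute system."""
    return reference_parameters(d=0.00001, sigma=0.001, a=0.001)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)


def interior_simplex_points(rng: np.random.Generator, n: int) -> np.ndarray:
    """n random points strictly inside the feasible simplex T (Dirichlet over s,e,i,r)."""
    return rng.dirichlet((1.0, 1.0, 1.0, 1.0), size=n)[:, :3]
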