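import numpy as np
import pytest

from bcrmix.params import GenParetoParams, MixtureParams, NegBinParams, make_params


@pytest.fixture
def hepb_params() -> MixtureParams:
    """Hepatitis-B-study-style parameter set (reported Γ, p, ω plus the
    package's documented count-parameter defaults)."""
    return make_params((0.992, 0.005, 0.003), 0.216, 0.970, 0.006, 0.277)


@pytest.fixture
def flu_params() -> MixtureParams:
    """Influenza-study-style parameter set; the quiescent regime has no
    high-abundance mass."""
    return make_params((0.947, 0.001, 0.052), 0.144, 0.144, 0.0, 0.486)


@pytest.fixture
def generic_params() -> MixtureParams:
    """Interior parameters convenient for enumeration-based checks."""
    return MixtureParams(
        gamma=(0.6, 0.25, 0.15),
        p_bgns=0.4,
        p_vs=0.8,
        q={"Q": 0.5, "A": 0.7},
        omega={"Q": 0.1, "A": 0.3},
        nb={"Q": NegBinParams(1.2, 0.9), "A": NegBinParams(4.0, 1.1)},
        gpd={"Q": GenParetoParams(0.4, 3.0, 1), "A": GenParetoParams(0.5, 8.0, 1)},
    )


@pytest.fixture
def small_tensor() -> np.ndarray:
    rng = np.random.default_rng(42)
    x = rng.integers(0, 5, size=(6, 2, 2))
    x[x == 4] = 12  # a couple of heavier counts
    x[0] = 0
    x[0, 0, 0] = 1  # keep every clone observed
    return x


def random_params(rng: np.random.Generator) -> MixtureParams:
    gamma = rng.dirichlet((5.0, 1.0, 1.0))
    return MixtureParams(
        gamma=tuple(gamma),
        p_bgns=float(rng.uniform(0.1, 0.6)),
        p_vs=float(rng.uniform(0.3, 0.95)),
        q={"Q": float(rng.uniform(0.2, 0.6)), "A": float(rng.uniform(0.4, 0.9))},
        omega={"Q": float(rng.uniform(0.0, 0.1)), "A": float(rng.uniform(0.1, 0.4))},
        nb={"Q": NegBinParams(float(rng.uniform(0.3, 2.0)), float(rng.uniform(0.4, 2.0))),
            "A": NegBinParams(float(rng.uniform(2.0, 6.0)), float(rng.uniform(0.5, 2.0)))},
        gpd={"Q": GenParetoParams(float(rng.uniform(0.1, 0.8)), float(rng.uniform(2, 15)), 1),
             "A": GenParetoParams(float(rng.uniform(0.2, 0.9)), float(rng.uniform(10, 50)), 1)},
    )
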