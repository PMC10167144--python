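import numpy as np
import pytest

from bayliss.kinematics import FiberFrame
from bayliss.params import ActiveParams, ChemParams, MaterialParams, PassiveParams


@pytest.fixture(scope="session")
def params() -> MaterialParams:
    return MaterialParams()


@pytest.fixture(scope="session")
def chem(params) -> ChemParams:
    return params.chem


@pytest.fixture(scope="session")
def active(params) -> ActiveParams:
    return params.active


@pytest.fixture(scope="session")
def passive(params) -> PassiveParams:
    return params.passive


@pytest.fixture(scope="session")
def frame30() -> FiberFrame:
    return FiberFrame.from_beta(30.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_spd(rng: np.random.Generator, spread: float = 0.15) -> np.ndarray:
    """Random right Cauchy-Green tensor near identity (always SPD)."""
    A = np.eye(3) + spread * rng.standard_normal((3, 3))
    C = A.T @ A
    return C / np.linalg.det(C) ** (1.0 / 3.0) * (1.0 + 0.05 * rng.standard_normal())
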