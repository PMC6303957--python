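import numpy as np
import pytest

from priorconf import ScenarioParams

# Reference-table scenarios used across test modules, keyed by printed row
# number.  Parameter tuples are (beta_zu, beta_xu, beta_yu); all rows share
# beta_xz = beta_yz = 1, beta_yx = 0, unit variances.
ROW_PARAMS = {
    1: (0, 0, 0),
    8: (1, 0, 1),
    9: (0, 1, 1),
    10: (1, 1, 1),
    11: (0, 2, 1),
    15: (0, 1, 2),
    16: (1, 1, 2),
    18: (1, 2, 2),
}


def row_scenario(row: int, n: int = 1000) -> ScenarioParams:
    beta_zu, beta_xu, beta_yu = ROW_PARAMS[row]
    return ScenarioParams(
        beta_yx=0.0,
        beta_yz=1.0,
        beta_yu=float(beta_yu),
        beta_xz=1.0,
        beta_xu=float(beta_xu),
        beta_zu=float(beta_zu),
        n=n,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def scenario8():
    return row_scenario(8)


@pytest.fixture
def scenario9():
    return row_scenario(9)
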