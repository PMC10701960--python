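import numpy as np
import pytest

from popdesign import (IndividualParams, ReferenceCurve, wtc_problem,
                       toy_problem)


@pytest.fixture(scope="session")
def fitted_params() -> IndividualParams:
    """The estimated WTC parameter set (fixed values plus fitted estimates)."""
    return IndividualParams()


@pytest.fixture(scope="session")
def base_reference() -> ReferenceCurve:
    """Linear reference through (0, 0) and (150, 60) nM, 25 nM dose step."""
    return ReferenceCurve()


@pytest.fixture(scope="session")
def wtc_prob():
    return wtc_problem()


@pytest.fixture(scope="session")
def toy_prob():
    """Constant-output toy problem: |k/d - 1| <= 0.5 viability."""
    return toy_problem(epsilon=0.5, r=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
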