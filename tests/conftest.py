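import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).resolve().parent))

from noncanon_pk.compartmental import MacroConstants, predict
from noncanon_pk.io import ConcProfile
from helpers import make_profile


@pytest.fixture
def rabbit_like_macro() -> MacroConstants:
    """Macro-constants in the range seen for a fast-cleared small peptide."""
    return MacroConstants(A=300.0, B=150.0, alpha=0.25, beta=0.03)


@pytest.fixture
def dense_schedule() -> np.ndarray:
    """The long i.v. sampling design (2–120 min)."""
    return np.array([2.0, 4.0, 6.0, 10.0, 20.0, 30.0, 60.0, 90.0, 120.0])


@pytest.fixture
def biexp_profile(rabbit_like_macro, dense_schedule) -> ConcProfile:
    """Noiseless samples lying exactly on a bi-exponential decay."""
    t = dense_schedule
    return make_profile(t, predict(rabbit_like_macro, t))


@pytest.fixture
def profile_factory():
    return make_profile
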