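import numpy as np
import pandas as pd
import pytest

from linecross import (
    SimConfig,
    build_cmatrix,
    simulate_dataset,
    standard_pedigree,
)
from linecross.pedigree import autocyto_effect_set


@pytest.fixture(scope="session")
def pedigrees():
    return standard_pedigree()


@pytest.fixture(scope="session")
def cmatrix_full(pedigrees):
    """Default 8 x 27 C-matrix (pooled sexes)."""
    return build_cmatrix(pedigrees)


@pytest.fixture(scope="session")
def cmatrix_autocyto(pedigrees):
    """Autosome+cytotype C-matrix matching the simulator's genetic system."""
    return build_cmatrix(pedigrees, autocyto_effect_set(pedigrees))


@pytest.fixture(scope="session")
def sim_dataset():
    """One simulated 8-line dataset under the default study conditions."""
    return simulate_dataset(SimConfig(), rng=20250926)


@pytest.fixture(scope="session")
def toy_cohorts():
    """Small hand-written cohort table for engine unit tests."""
    return pd.DataFrame({
        "cohort": ["P1", "P2", "F1", "rF1", "BC1", "rBC1", "BC2", "rBC2"],
        "mean": [0.05, 0.60, 0.62, 0.64, 0.30, 0.33, 0.55, 0.58],
        "se": [0.02, 0.05, 0.05, 0.05, 0.046, 0.047, 0.05, 0.049],
        "n": [100] * 8,
    })


def wss_bruteforce(y, se, X, beta):
    """Direct evaluation of the weighted sum of squares."""
    r = y - X @ beta
    return float(np.sum(r * r / se**2))
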