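import numpy as np
import pandas as pd
import pytest

from pnmeth import BetaMatrix, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (3 x 30 tumours, 11 normals, 5000 probes)."""
    return simulate_cohort(SimConfig(seed=1))


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free cohort (flip_noise = 0) for exact-recovery checks."""
    return simulate_cohort(SimConfig(seed=2, flip_noise=0.0))


@pytest.fixture()
def tiny_beta():
    """2 probes x 3 samples (2 tumours + 1 normal) hand-set beta matrix."""
    values = pd.DataFrame(
        [[0.10, 0.90, 0.05], [0.50, 0.20, 0.25]],
        index=["cg1", "cg2"],
        columns=["t1", "t2", "n1"],
    )
    roles = pd.Series({"t1": "tumour", "t2": "tumour", "n1": "normal"})
    return BetaMatrix(values, roles)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
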