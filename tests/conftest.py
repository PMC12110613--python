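import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from mutsig import CohortSpec, simulate_cohort, simulate_signatures
from mutsig.channels import ChannelScheme


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture(scope="session")
def planted_signatures():
    """Three well-separated SBS96 signature profiles."""
    return simulate_signatures(96, 3, concentration=0.1, seed=11)


@pytest.fixture(scope="session")
def small_cohort(planted_signatures):
    """60-sample cohort with ~1000 mutations/sample from 3 planted signatures."""
    spec = CohortSpec(
        n_samples=60,
        signatures=planted_signatures,
        scheme=ChannelScheme.SBS96,
        burden_mean=1000.0,
        seed=12,
    )
    return simulate_cohort(spec)
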