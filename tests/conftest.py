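import numpy as np
import pytest

from twosite.globalfit import GlobalFitConfig
from twosite.synthetic import ConditionGrid, GroundTruth, gen_rd_dataset

TABLE_TEMPS_K = [278.15, 283.15, 288.15, 293.15]
# Published per-temperature rate constants of the thermophilic construct and
# of the mesophilic S191A mutant (forward a->b on top, backward b->a below).
KAB_TEIN = [171.0, 265.0, 406.0, 613.0]
KBA_TEIN = [1946.0, 2897.0, 4255.0, 6168.0]
KAB_S191A = [361.0, 554.0, 837.0, 1249.0]
PB_TEIN = [0.081, 0.084, 0.087, 0.090]

DG_ACT_TRUE = 50_228.0
DG_EQ_TRUE = 5_601.0


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free dispersion dataset at the default study conditions."""
    return gen_rd_dataset(GroundTruth(noise_sd=0.0, seed=11))


@pytest.fixture(scope="session")
def noisy_dataset():
    """Dispersion dataset with 0.2 1/s Gaussian noise, fixed seed."""
    return gen_rd_dataset(GroundTruth(noise_sd=0.2, seed=2024))


@pytest.fixture
def fast_fit_config():
    return GlobalFitConfig(multistart_count=3, seed=0)
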