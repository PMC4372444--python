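import numpy as np
import pytest

from memnmr import shift_data, synthetic_data
from memnmr.synthetic_data import GHRELIN_SEQUENCE, PoolRecipe, gen_pool

RESTRAINT_ATOMS = ("CO", "CA", "CB", "HA")


@pytest.fixture(scope="session")
def exp_table():
    """The packaged experimental shift table."""
    return shift_data.read_shift_table(shift_data.packaged_shift_table_path())


@pytest.fixture(scope="session")
def rc_reference():
    return shift_data.load_random_coil_reference()


@pytest.fixture(scope="session")
def small_pool():
    """8 synthetic models, fixed seed: small enough for exhaustive oracles."""
    return gen_pool(PoolRecipe(n_models=8, seed=3, class_mix=(0.5, 0.2, 0.3)))


@pytest.fixture(scope="session")
def medium_pool():
    """200 synthetic models with a mixed class composition."""
    return gen_pool(
        PoolRecipe(n_models=200, seed=11, class_mix=(0.5, 0.2, 0.3), z_range=(0.0, 30.0))
    )


@pytest.fixture(scope="session")
def recovery_pool():
    """500-model helix/coil pool used by the ensemble-recovery properties."""
    return gen_pool(
        PoolRecipe(n_models=500, seed=42, class_mix=(0.7, 0.0, 0.3), shift_sigma=0.3)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
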