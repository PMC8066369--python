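import numpy as np
import pytest

from sliceforest import (
    BankConfig,
    Cohort,
    PhantomConfig,
    Volume,
    generate_cohort,
    train_bank,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_cohort(rng):
    """Six random labeled volumes of shape (4, 5, 6)."""
    volumes = [
        Volume(rng.normal(100, 5, (4, 5, 6)), subject_id=f"s{i}", label=i % 2)
        for i in range(6)
    ]
    return Cohort(volumes)


TINY_PHANTOM = PhantomConfig(
    shape=(8, 9, 8),
    n_controls=6,
    n_patients=6,
    lesions=(((2, 5), (3, 6), (2, 5)),),
    effect=10.0,
    noise_sd=0.0,
    baseline="flat",
    seed=7,
)

TINY_BANK = BankConfig(n_trees=20, seed=11)


@pytest.fixture(scope="session")
def tiny_phantom():
    """Noise-free separable phantom: flat baseline, 3x3x3-slice lesion."""
    return generate_cohort(TINY_PHANTOM)


@pytest.fixture(scope="session")
def tiny_bank(tiny_phantom):
    return train_bank(tiny_phantom.cohort, TINY_BANK)
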