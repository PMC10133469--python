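import dataclasses

import numpy as np
import pytest

from rumenpls.bayes import ChainSpec
from rumenpls.compositional import clr_transform, prevalence_filter, replace_zeros
from rumenpls.simulate import SimConfig, generate_dataset

# Desk-scale study emulation used by most tests: 26 samples, fewer genera
# and reduced depth so the whole chain runs in seconds, with strong diet
# and methane-driver signal for recovery checks.
QUICK = SimConfig(
    n_per_diet=13,
    n_genera=60,
    n_diet_affected=10,
    diet_effect_size=3.0,
    n_methane_drivers_per_diet=3,
    methane_coefficients=(2.5, -2.0, 1.5),
    methane_noise_sd=1.0,
    sequencing_depth_mean=20_000,
    seed=7,
)

# Strong-signal fixture at full study scale (203 genera, 22 shifted genera,
# 5 drivers per diet with a cross-over genus).
STRONG = SimConfig(diet_effect_size=3.0, methane_noise_sd=1.0, seed=1)

# No-effect condition: no diet-shifted genera, no methane drivers, noise
# only; used for null calibrations.
NULL = dataclasses.replace(
    QUICK,
    n_diet_affected=0,
    methane_coefficients=(0.0, 0.0, 0.0),
    breed_effect=0.0,
    bodyweight_slope=0.0,
    seed=11,
)

# Short chain for tests: 5,000 saved samples like the full default.
FAST_CHAIN = ChainSpec(iterations=6_000, burn_in=1_000, thin=1, seed=0)


@pytest.fixture(scope="session")
def quick_dataset():
    return generate_dataset(QUICK)


@pytest.fixture(scope="session")
def quick_clr(quick_dataset):
    filtered = prevalence_filter(quick_dataset.counts, 0.2)
    return clr_transform(replace_zeros(filtered))


@pytest.fixture(scope="session")
def strong_dataset():
    return generate_dataset(STRONG)


@pytest.fixture(scope="session")
def null_dataset():
    return generate_dataset(NULL)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
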