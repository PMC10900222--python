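"""Shared fixtures.

The heavy end-to-end experiments are session-scoped so that the
acceptance tests and any unit test needing the same artifacts run them
once.  All randomness is seeded.
"""

import numpy as np
import pytest

from allokin import pipelines
from allokin.synthetic_data import BrownianConfig, TorsionPotential

#: seed of record for the test-suite experiments
SEED = 0


@pytest.fixture(scope="session")
def wham_experiment():
    return pipelines.wham_recovery_experiment(SEED)


@pytest.fixture(scope="session")
def extrapolation_experiment():
    return pipelines.extrapolation_recovery_experiment(SEED)


@pytest.fixture(scope="session")
def kinetics_experiment():
    return pipelines.kinetics_recovery_experiment(SEED)


@pytest.fixture(scope="session")
def kramers_experiment():
    return pipelines.kramers_recovery_experiment(SEED)


@pytest.fixture(scope="session")
def modes_experiment():
    return pipelines.modes_recovery_experiment(SEED)


@pytest.fixture
def double_well_84():
    """The 8.4 kcal/mol double well (a scaled prolyl barrier)."""
    return TorsionPotential(terms=((2, 8.4, 180.0),))


@pytest.fixture
def quick_cfg():
    """Short Brownian run for cheap structural tests."""
    return BrownianConfig(
        d_true=pipelines.D_TRUE, timestep=pipelines.DT,
        n_steps=20_000, save_stride=10, seed=SEED,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
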