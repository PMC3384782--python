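import warnings

import numpy as np
import pytest

from jointlgm.model import JointModel
from jointlgm.preprocess import apply_exclusions, cycle_average
from jointlgm.simulate import simulate_cohort, table4_asbi5_config


@pytest.fixture(scope="session")
def default_cohort():
    """Small synthetic trial under the default study conditions."""
    return simulate_cohort(table4_asbi5_config(n_subjects=60, seed=23))


@pytest.fixture(scope="session")
def default_obs(default_cohort):
    obs = cycle_average(default_cohort.longitudinal)
    obs, _ = apply_exclusions(obs, default_cohort.survival)
    return obs


@pytest.fixture(scope="session")
def recovery_fit():
    """Full-size shared random-effects fit used by the recovery checks.

    One n=448 cohort under the default study conditions, fitted with the
    quadratic slope-treatment spec and standard errors.
    """
    cohort = simulate_cohort(table4_asbi5_config(n_subjects=448, seed=1))
    model = JointModel.from_cohort(cohort, spec="q_s", link="shared_re",
                                   quad_nodes=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit()
    return cohort, res


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
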