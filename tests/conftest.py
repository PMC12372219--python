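import numpy as np
import pandas as pd
import pytest

from driftchoice import simulate
from driftchoice.preprocessing import apply_exclusions
from driftchoice.task_design import standardize_covariates


@pytest.fixture(scope="session")
def design_df():
    return standardize_covariates()


@pytest.fixture(scope="session")
def small_study():
    """Tiny two-group study: 4 control + 4 sud participants."""
    trials, truth = simulate.simulate_study(
        simulate.control_like_spec(4, rng_seed=1),
        simulate.sud_like_spec(4, rng_seed=2),
        rng_seed=123, contaminate=0.01)
    return trials, truth


@pytest.fixture(scope="session")
def retained_small(small_study):
    trials, _ = small_study
    retained, _ = apply_exclusions(trials)
    return retained


@pytest.fixture(scope="session")
def tiny_fit(retained_small, design_df):
    """A short M3 fit on the control group, reused across tests."""
    from driftchoice.inference import HierarchicalDDM
    sub = retained_small[retained_small["group"] == "control"]
    return HierarchicalDDM(model="M3", n_draws=300, n_burn=150, n_chains=2,
                           seed=9).fit(sub, design_df)
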