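import numpy as np
import pytest

from bigjm.basis import place_knots
from bigjm.data_io import validate_join
from bigjm.likelihood import ModelSpec, PriorSpec
from bigjm.mcmc import McmcConfig
from bigjm.pooling import fit_big
from bigjm.simulate import SimulationConfig, simulate_joint_dataset

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=25)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def sim_small():
    """80-subject cohort at the default generating values."""
    return simulate_joint_dataset(SimulationConfig(n_subjects=80, seed=7))


@pytest.fixture(scope="session")
def ds_small(sim_small):
    long, surv, _ = sim_small
    return validate_join(long, surv)


@pytest.fixture(scope="session")
def basis_small(sim_small):
    _, surv, _ = sim_small
    ev = surv.records.loc[surv.records["event"] == 1, "observed_time"].to_numpy()
    return place_knots(ev, 2)


@pytest.fixture(scope="session")
def spec_default():
    return ModelSpec()


@pytest.fixture(scope="session")
def priors_default():
    return PriorSpec()


@pytest.fixture(scope="session")
def fitted_small():
    """A 200-subject single-chunk fit shared by prediction/evaluation tests."""
    long, surv, truth = simulate_joint_dataset(SimulationConfig(n_subjects=200, seed=3))
    pooled = fit_big(
        long,
        surv,
        mcmc=McmcConfig(n_iter=1500, n_burnin=500),
        chunk_size=200,
        seed=3,
        keep_draws=True,
    )
    return long, surv, truth, pooled
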