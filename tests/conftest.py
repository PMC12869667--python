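import numpy as np
import pytest

from msinet.cohorts import COHORT_NAMES, CohortSpec, run_cohort
from msinet.params import LearningRates, get_preset
from msinet.plasticity import TrainingSchedule, train_logged
from msinet.stimuli import MixSpec

#: Suite-wide seed for every stochastic component.
SEED = 1


@pytest.fixture(scope="session")
def td_params():
    return get_preset("td_child")


@pytest.fixture(scope="session")
def asd_params():
    return get_preset("asd_child")


@pytest.fixture(scope="session")
def adult_params():
    return get_preset("adult")


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def cohort_results():
    """All seven developmental cohorts, trained once per session.

    Maps cohort name -> (RTTrajectory, [(epoch, NetworkParams), ...]).
    """
    out = {}
    for name in COHORT_NAMES:
        traj, ckpts = run_cohort(
            CohortSpec.named(name), seed=SEED, return_checkpoints=True
        )
        out[name] = (traj, ckpts)
    return out


@pytest.fixture(scope="session")
def td_training_log():
    """Typical-development training with the full per-epoch weight log."""
    schedule = TrainingSchedule(
        mix_schedule=[(0, MixSpec(0.30, 0.20, 0.50))], rates=LearningRates()
    )
    rng = np.random.default_rng(SEED)
    return train_logged(get_preset("td_child"), schedule, rng)
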