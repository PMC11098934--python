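import numpy as np
import pytest

from interblock.anova import AnovaOperator
from interblock.design import generate_alpha_design
from interblock.simulate import (
    DEFAULT_PRIOR,
    SimulationScenario,
    _simulate_collection,
    simulate_trial,
)


@pytest.fixture(scope="session")
def layout_a():
    """The small-block alpha design: 6 varieties, 2 replicates, blocks of 3."""
    return generate_alpha_design(6, 2, 3, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def sim_trial_a(layout_a):
    """One seeded simulated trial on the small alpha design."""
    return simulate_trial(layout_a, DEFAULT_PRIOR(), 1.0, np.random.default_rng(42))


@pytest.fixture(scope="session")
def collection_a():
    """60 simulated scenario-A trials with their ANOVA summaries."""
    sc = SimulationScenario.scenario_a(n_trials=60, seed=5)
    trials, summaries, _ = _simulate_collection(sc)
    return trials, summaries


@pytest.fixture(scope="session")
def collection_informative():
    """120 trials on an information-rich layout (t=12, r=8, k=4).

    The replicate stratum of any 2-replicate design has a single degree of
    freedom, so hyper-parameter-level checks use this layout instead.
    """
    sc = SimulationScenario(n_trials=120, t=12, r=8, k=4, seed=11)
    trials, summaries, _ = _simulate_collection(sc)
    return trials, summaries


@pytest.fixture(scope="session")
def operator_a(layout_a):
    return AnovaOperator(layout_a)
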