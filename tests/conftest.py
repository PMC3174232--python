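import numpy as np
import pytest

from namsite import (
    SyntheticScenario,
    gen_conformation_ensemble,
    gen_pose_cloud,
    gen_receptor,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def small_scenario():
    """Three conformations, 60 poses each: fast but structurally complete."""
    return SyntheticScenario(seed=7, n_conformations=3, n_poses_per_conformation=60)


@pytest.fixture(scope="session")
def small_receptor(small_scenario):
    return gen_receptor(small_scenario)


@pytest.fixture(scope="session")
def small_ensemble(small_scenario, small_receptor):
    return gen_conformation_ensemble(
        small_receptor,
        small_scenario.n_conformations,
        small_scenario.conformation_jitter_sd,
        small_scenario.seed,
    )


@pytest.fixture(scope="session")
def small_pose_sets(small_scenario):
    return [
        gen_pose_cloud(small_scenario, i)
        for i in range(small_scenario.n_conformations)
    ]
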