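import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from strigamet import simdata

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


def small_env_set():
    return [
        simdata.Environment("Abuja", 2016, "infested"),
        simdata.Environment("Mokwa", 2016, "infested"),
        simdata.Environment("Abuja", 2017, "free"),
        simdata.Environment("Mokwa", 2017, "free"),
    ]


@pytest.fixture(scope="session")
def small_design():
    """60-entry, 4-environment trial: fast but structurally identical to the
    full 156-entry lattice."""
    return simdata.TrialDesign(
        n_hybrids=57,
        n_checks=3,
        block_size=6,
        blocks_per_rep=10,
        environments=small_env_set(),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_trial(small_design):
    truth = simdata.GroundTruth.default(small_design.n_entries, seed=11)
    return simdata.simulate_trial(small_design, truth)


@pytest.fixture(scope="session")
def default_design():
    return simdata.TrialDesign(seed=1)


@pytest.fixture(scope="session")
def default_trial(default_design):
    """Full-size trial: 156 entries x 7 environments x 2 reps = 2184 plots."""
    truth = simdata.GroundTruth.default(default_design.n_entries, seed=1)
    return simdata.simulate_trial(default_design, truth)


def balanced_toy(n_entries=2, n_envs=2, n_reps=2, values=None, seed=0):
    """Complete balanced layout with one (trivial) block per replicate."""
    rows = []
    for j in range(n_envs):
        for k in range(1, n_reps + 1):
            for i in range(n_entries):
                rows.append((f"E{j}", "loc", 2016, "free", k, 1, f"G{i}"))
    df = pd.DataFrame(
        rows, columns=["env", "location", "year", "treatment", "rep", "block", "entry"]
    )
    if values is None:
        rng = np.random.default_rng(seed)
        values = rng.integers(1, 20, len(df)).astype(float)
    df["y"] = np.asarray(values, dtype=float)
    return df
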