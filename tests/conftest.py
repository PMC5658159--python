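"""Shared fixtures: packaged count table, small simulated trials, worlds."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from strokemsm import datasets
from strokemsm.panel import StateSpace, TrialPanel
from strokemsm.simulate import SimulationSpec, simulate_trial


@pytest.fixture(scope="session")
def ninds_counts() -> pd.DataFrame:
    return datasets.ninds_mrs90_counts()


@pytest.fixture(scope="session")
def ninds_panel() -> TrialPanel:
    return datasets.ninds_mrs90_panel()


@pytest.fixture(scope="session")
def ss3() -> StateSpace:
    """Small 3-state space without death, for fast Markov fits."""
    return StateSpace(states=(0, 1, 2), absorbing=frozenset(),
                      allowed=frozenset({(0, 1), (1, 0), (1, 2), (2, 1)}))


def dense_world(seed: int, n_per_arm: int = 100,
                treatment_log_hr=None) -> SimulationSpec:
    """Time-homogeneous mRS world with events on all 12 transitions.

    Rates and a spread-out initial distribution are chosen so every allowed
    transition is actually observed at n ~ 100/arm — the information-dense
    regime in which chi-square asymptotics for the 12-df global test apply.
    """
    ints = {}
    for r in range(1, 6):
        ints[(r, r - 1)] = 0.020
    for r in range(0, 5):
        ints[(r, r + 1)] = 0.012
    ints[(4, 6)] = 0.006
    ints[(5, 6)] = 0.012
    return SimulationSpec(
        n_per_arm=n_per_arm, seed=seed, intensities=(ints,), breakpoints=(),
        initial_state_dist=(0.05, 0.15, 0.2, 0.2, 0.2, 0.2),
        treatment_log_hr=treatment_log_hr or {})


@pytest.fixture(scope="session")
def effect_trial():
    """NINDS-scale trial with a protective effect on the 1->2 transition."""
    spec = SimulationSpec(n_per_arm=150, seed=11,
                          treatment_log_hr={(1, 2): np.log(0.5),
                                            (2, 1): np.log(1.4)})
    return simulate_trial(spec)


@pytest.fixture(scope="session")
def null_trial():
    """NINDS-scale trial with no treatment effect."""
    return simulate_trial(SimulationSpec(n_per_arm=150, seed=29))
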