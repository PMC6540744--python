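"""Shared fixtures.

The expensive Monte-Carlo runs (20 000 replicates at the reference study
conditions) are session-scoped so that the bias/MSE assertions across the
suite reuse a single simulated data stream.
"""
from __future__ import annotations

import numpy as np
import pytest

import selectest as st
from selectest.simulation import SimulationScenario, evaluate_estimators, run_sigma_study

MC_REPS = 20_000
MC_SEED = 20180105  # fixed; all suite randomness flows from here


@pytest.fixture
def worked_ranked():
    """Hand-computed k=2 example: rank-1 values {1,−1}, rank-2 {0.9,−1.1},
    one stage-2 observation Ȳ=0.  UMVCUE ≈ −0.71650."""
    trial = st.trial_from_values([[1.0, -1.0], [0.9, -1.1]], {0: [0.0]})
    return st.rank_and_relabel(trial)


@pytest.fixture
def boundary_ranked():
    """k=2 boundary case {2,0}/{0,0}, Y=1: r̲=1, q̲=−1, zero correction."""
    trial = st.trial_from_values([[2.0, 0.0], [0.0, 0.0]], {0: [1.0]})
    return st.rank_and_relabel(trial)


def make_random_ranked(rng: np.random.Generator, k: int | None = None,
                       equal_n: int | None = None, m: int | None = None):
    """A random valid ranked trial with stage-2 data on rank 1."""
    k = k or int(rng.integers(2, 6))
    if equal_n is not None:
        sizes = [equal_n] * k
    else:
        sizes = [int(rng.integers(2, 9)) for _ in range(k)]
    mu = rng.normal(0, 1, k)
    stage1 = [list(rng.normal(mu[i], 1, sizes[i])) for i in range(k)]
    order = np.argsort([-float(np.mean(v)) for v in stage1])
    m = m if m is not None else int(rng.integers(1, 9))
    stage2 = {int(order[0]): list(rng.normal(mu[order[0]], 1, m))}
    return st.rank_and_relabel(st.trial_from_values(stage1, stage2))


@pytest.fixture(scope="session")
def reference_scenario():
    """The reference study conditions: k=3 null arms, σ²=1, n=m=10,
    rank-1 selection by largest stage-1 mean."""
    return SimulationScenario(true_means=(0.0, 0.0, 0.0), sigma2=1.0,
                              stage1_sizes=(10, 10, 10), stage2_sizes={1: 10},
                              select_ranks=(1,), n_reps=MC_REPS, seed=MC_SEED)


@pytest.fixture(scope="session")
def reference_run(reference_scenario):
    """All four estimators at the reference conditions, pooled plug-in."""
    return evaluate_estimators(
        reference_scenario,
        ["mle", "stage2", "umvcue_unknown", "umvcue_known"],
        plug_in_sigma2="pooled")


def _mle_run(m_per_group: int) -> st.SimulationResult:
    scen = SimulationScenario(true_means=(0.0, 0.0, 0.0), sigma2=1.0,
                              stage1_sizes=(m_per_group,) * 3,
                              stage2_sizes={1: m_per_group},
                              select_ranks=(1,), n_reps=MC_REPS, seed=MC_SEED + m_per_group)
    return evaluate_estimators(scen, ["mle"])


@pytest.fixture(scope="session")
def mle_run_m4():
    """MLE at the smallest design point on the power grid (M=4)."""
    return _mle_run(4)


@pytest.fixture(scope="session")
def mle_run_m12():
    """MLE at the largest design point on the power grid (M=12)."""
    return _mle_run(12)


@pytest.fixture(scope="session")
def sigma_study_table():
    """Plug-in sensitivity study on a scaled-down grid (5 values)."""
    return run_sigma_study([0.25, 0.5, 1.0, 2.0, 4.0], M=10,
                           n_reps=MC_REPS, seed=MC_SEED + 1)
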