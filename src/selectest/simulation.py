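"""Synthetic-trial generator and Monte-Carlo evaluation studies.

Trials are drawn from the sampling model of the estimators: k arms with
normal outcomes, common variance, interim ranking by stage-1 sample means,
and stage-2 follow-up only on the selected ranks.  Selection-conditional
bias and MSE are accumulated replicate-wise as (estimate − true mean of the
arm occupying the evaluated rank), which realises the selection-weighted
definitions

    b_sel  = Σ_i E[μ̂ − μ_i | arm i selected] P(arm i selected)
    MSE_sel = Σ_i E[(μ̂ − μ_i)² | arm i selected] P(arm i selected)

without enumerating selection events.

RNG streams are keyed (seed, replicate, arm, stage) through a SeedSequence,
so a trial is fully determined by (seed, replicate) and the data stream is
untouched by which estimators are evaluated.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import InvalidTrialError, SelectestError, TieWarning
from .estimators import (
    mle,
    pooled_variance,
    stage2_estimate,
    umvcue_known,
    umvcue_unknown,
)
from .power import PowerSpec, min_per_group_size
from .trial_model import (
    Arm,
    ArmStageSummary,
    RankedTrial,
    TwoStageTrial,
    rank_and_relabel,
)

#: study conditions of the reference evaluation: k = 3 null arms, unit
#: variance, per-group per-stage size 10 (the 90%-power design point)
DEFAULT_K = 3
DEFAULT_MEANS = (0.0, 0.0, 0.0)
DEFAULT_SIGMA2 = 1.0
DEFAULT_M = 10
DEFAULT_N_REPS = 100_000


@dataclass(frozen=True)
class SimulationScenario:
    """Complete description of a simulated two-stage selection trial."""

    true_means: tuple[float, ...] = DEFAULT_MEANS
    sigma2: float = DEFAULT_SIGMA2
    stage1_sizes: tuple[int, ...] = (DEFAULT_M,) * DEFAULT_K
    stage2_sizes: Mapping[int, int] = field(default_factory=lambda: {1: DEFAULT_M})
    select_ranks: tuple[int, ...] = (1,)
    ranking_rule: str = "sample-mean"
    n_reps: int = DEFAULT_N_REPS
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.true_means)
        if len(self.stage1_sizes) != k:
            raise InvalidTrialError("stage1_sizes length must match true_means")
        if self.sigma2 < 0:
            raise InvalidTrialError("sigma2 must be >= 0")
        for r in self.select_ranks:
            if not 1 <= r <= k:
                raise InvalidTrialError(f"selected rank {r} outside 1..{k}")
            if self.stage2_sizes.get(r, 0) < 1:
                raise InvalidTrialError(f"selected rank {r} needs stage-2 size >= 1")

    @property
    def k(self) -> int:
        return len(self.true_means)


def _rng(seed: int, rep: int, arm: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, rep, arm, stage)))


def simulate_trial(scenario: SimulationScenario, rep_index: int) -> RankedTrial:
    """Draw one replicate.  (seed, rep_index) fully determines the trial."""
    sigma = math.sqrt(scenario.sigma2)
    k = scenario.k
    stage1 = [
        scenario.true_means[i]
        + sigma * _rng(scenario.seed, rep_index, i, 1).standard_normal(scenario.stage1_sizes[i])
        for i in range(k)
    ]
    # interim ranking on stage-1 means (stage-2 not yet drawn)
    if scenario.ranking_rule == "p-value":
        stats = [math.sqrt(len(v)) * v.mean() for v in stage1]
    else:
        stats = [v.mean() for v in stage1]
    order = sorted(range(k), key=lambda i: (-stats[i], i))

    stage2: dict[int, np.ndarray] = {}
    for rank in scenario.select_ranks:
        arm_idx = order[rank - 1]
        m = scenario.stage2_sizes[rank]
        stage2[arm_idx] = (
            scenario.true_means[arm_idx]
            + sigma * _rng(scenario.seed, rep_index, arm_idx, 2).standard_normal(m)
        )

    arms = tuple(
        Arm(label=f"arm{i + 1}",
            stage1=ArmStageSummary.from_values(stage1[i]),
            stage2=(ArmStageSummary.from_values(stage2[i]) if i in stage2 else None),
            raw_stage1=tuple(stage1[i]),
            raw_stage2=tuple(stage2[i]) if i in stage2 else None)
        for i in range(k)
    )
    with warnings.catch_warnings():
        if scenario.sigma2 == 0:
            warnings.simplefilter("ignore", TieWarning)
        return rank_and_relabel(TwoStageTrial(arms=arms), scenario.ranking_rule)


def _estimate(tag: str, ranked: RankedTrial, rank: int,
              plug_in_sigma2: Union[float, str]) -> float:
    if tag == "mle":
        return mle(ranked, rank).estimate
    if tag == "stage2":
        return stage2_estimate(ranked, rank).estimate
    if tag == "umvcue_unknown":
        return umvcue_unknown(ranked, rank).estimate
    if tag == "umvcue_known":
        s2 = pooled_variance(ranked, rank) if plug_in_sigma2 == "pooled" else float(plug_in_sigma2)
        return umvcue_known(ranked, rank, math.sqrt(s2)).estimate
    raise InvalidTrialError(f"unknown estimator tag {tag!r}")


@dataclass(frozen=True)
class SimulationResult:
    """Selection-conditional bias and MSE per (estimator, rank), with
    Monte-Carlo standard errors."""

    table: dict  # (estimator, rank) -> dict(bias, mse, mc_se_bias, mc_se_mse)
    n_reps_used: int
    n_failures: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"estimator": tag, "rank": rank, **cell,
             "n_reps": self.n_reps_used, "seed": self.seed}
            for (tag, rank), cell in sorted(self.table.items())
        ]
        return pd.DataFrame(rows)


def _summarise(errors: np.ndarray) -> dict:
    n = errors.size
    sq = errors**2
    return {
        "bias": float(errors.mean()),
        "mse": float(sq.mean()),
        "mc_se_bias": float(errors.std(ddof=1) / math.sqrt(n)),
        "mc_se_mse": float(sq.std(ddof=1) / math.sqrt(n)),
    }


def evaluate_estimators(scenario: SimulationScenario,
                        estimators: Sequence[str],
                        plug_in_sigma2: Union[float, str] = "pooled") -> SimulationResult:
    """Monte-Carlo selection-conditional bias and MSE of the given estimators.

    The error in each replicate is measured against the true mean of the arm
    occupying the evaluated rank.  A replicate in which an estimator fails
    (degenerate data) is excluded for all estimators and counted; more than
    0.1% failures aborts the run.
    """
    errors: dict[tuple[str, int], list[float]] = {
        (tag, r): [] for tag in estimators for r in scenario.select_ranks}
    failures = 0
    for rep in range(scenario.n_reps):
        ranked = simulate_trial(scenario, rep)
        try:
            cell = {}
            for rank in scenario.select_ranks:
                mu_true = scenario.true_means[ranked.order[rank - 1]]
                for tag in estimators:
                    est = _estimate(tag, ranked, rank, plug_in_sigma2)
                    cell[(tag, rank)] = est - mu_true
        except SelectestError as exc:
            failures += 1
            warnings.warn(f"replicate {rep} excluded: {exc}", stacklevel=2)
            continue
        for key, err in cell.items():
            errors[key].append(err)
    if failures > max(1, scenario.n_reps) * 1e-3:
        raise SelectestError(
            f"{failures} of {scenario.n_reps} replicates failed (> 0.1%)")
    table = {key: _summarise(np.asarray(errs)) for key, errs in errors.items()}
    return SimulationResult(table=table, n_reps_used=scenario.n_reps - failures,
                            n_failures=failures, seed=scenario.seed)


_STUDY_ESTIMATORS = ("mle", "stage2", "umvcue_unknown", "umvcue_known")


def _equal_size_scenario(m_per_group: int, k: int = DEFAULT_K,
                         true_means: Optional[Sequence[float]] = None,
                         sigma2: float = DEFAULT_SIGMA2,
                         n_reps: int = DEFAULT_N_REPS, seed: int = 0) -> SimulationScenario:
    mu = tuple(true_means) if true_means is not None else (0.0,) * k
    return SimulationScenario(true_means=mu, sigma2=sigma2,
                              stage1_sizes=(m_per_group,) * k,
                              stage2_sizes={1: m_per_group},
                              select_ranks=(1,), n_reps=n_reps, seed=seed)


def run_power_study(beta_grid: Sequence[float],
                    alpha: float = 0.05, lam: float = 0.5, k: int = DEFAULT_K,
                    n_reps: int = DEFAULT_N_REPS, seed: int = 0) -> pd.DataFrame:
    """Bias/MSE of the four estimators across target powers.

    Each β on the grid is converted to the per-group size M by the design
    rule; the scenario is k null arms with unit variance, n = m = M, rank-1
    selection, and the known-variance estimator uses the pooled plug-in.
    """
    if len(beta_grid) == 0:
        raise ValueError("beta_grid must be nonempty")
    rows = []
    for i, beta in enumerate(beta_grid):
        m_size = min_per_group_size(PowerSpec(alpha=alpha, beta=beta, lam=lam, k=k))
        scen = _equal_size_scenario(m_size, k=k, n_reps=n_reps, seed=seed + i)
        res = evaluate_estimators(scen, _STUDY_ESTIMATORS, plug_in_sigma2="pooled")
        for (tag, rank), cell in sorted(res.table.items()):
            rows.append({"beta": beta, "power": 1.0 - beta, "M": m_size,
                         "estimator": tag, "rank": rank, **cell,
                         "n_reps": res.n_reps_used, "seed": scen.seed})
    return pd.DataFrame(rows)


def run_sigma_study(sigma2_grid: Sequence[float], M: int = DEFAULT_M,
                    n_reps: int = DEFAULT_N_REPS, seed: int = 0) -> pd.DataFrame:
    """Sensitivity of the known-variance estimator to a mis-specified plug-in.

    The scenario is fixed (k = 3 null arms, σ² = 1, n = m = M); each grid
    value is plugged into the known-variance formula while the MLE, stage-2
    and unknown-variance estimators — which ignore the plug-in — are computed
    once per replicate and shared across the grid.
    """
    grid = [float(g) for g in sigma2_grid]
    if any(g <= 0 for g in grid):
        raise ValueError("plug-in variances must be positive")
    scen = _equal_size_scenario(M, n_reps=n_reps, seed=seed)
    base_tags = ("mle", "stage2", "umvcue_unknown")
    errors: dict = {tag: [] for tag in base_tags}
    errors.update({("umvcue_known", g): [] for g in grid})
    for rep in range(scen.n_reps):
        ranked = simulate_trial(scen, rep)
        mu_true = scen.true_means[ranked.order[0]]
        for tag in base_tags:
            errors[tag].append(_estimate(tag, ranked, 1, "pooled") - mu_true)
        for g in grid:
            errors[("umvcue_known", g)].append(
                umvcue_known(ranked, 1, math.sqrt(g)).estimate - mu_true)
    rows = []
    for g in grid:
        for tag in base_tags:
            rows.append({"plug_in_sigma2": g, "estimator": tag,
                         **_summarise(np.asarray(errors[tag]))})
        rows.append({"plug_in_sigma2": g, "estimator": "umvcue_known",
                     **_summarise(np.asarray(errors[("umvcue_known", g)]))})
    df = pd.DataFrame(rows)
    df["M"] = M
    df["n_reps"] = scen.n_reps
    df["seed"] = seed
    return df


#: the COPD dose-finding illustration: treatment differences vs placebo (L)
#: for three doses, small-sample sizes, outcome SD 0.3 L
CASE_STUDY_LABELS = ("75", "150", "300")
CASE_STUDY_MEANS = (0.15, 0.18, 0.21)
CASE_STUDY_STAGE1_SIZES = (10, 9, 7)
CASE_STUDY_STAGE2_SIZE = 9
CASE_STUDY_SD = 0.3


def case_study_scenario(seed: int) -> SimulationScenario:
    """Dose-finding scenario: three doses with true treatment differences
    (0.15, 0.18, 0.21) L, SD 0.3 L, stage-1 sizes (10, 9, 7), the top two
    ranks continued with 9 subjects each."""
    return SimulationScenario(true_means=CASE_STUDY_MEANS,
                              sigma2=CASE_STUDY_SD**2,
                              stage1_sizes=CASE_STUDY_STAGE1_SIZES,
                              stage2_sizes={1: CASE_STUDY_STAGE2_SIZE,
                                            2: CASE_STUDY_STAGE2_SIZE},
                              select_ranks=(1, 2), n_reps=1, seed=seed)


def run_case_study(seed: int = 0) -> pd.DataFrame:
    """Simulate one realisation of the dose-finding trial and report all
    estimators for the two continued ranks.

    Columns mirror a dose-selection report: stage-1 and stage-2 sample means,
    the weighted-mean MLE, and the two bias-corrected estimators (the
    known-variance one with the pooled plug-in).
    """
    scen = case_study_scenario(seed)
    ranked = simulate_trial(scen, 0)
    rows = []
    for rank in (1, 2):
        arm = ranked.arm(rank)
        label = CASE_STUDY_LABELS[ranked.order[rank - 1]]
        rows.append({
            "rank": rank,
            "dose_ug": label,
            "n1": arm.stage1.count,
            "stage1": arm.stage1.mean,
            "m": arm.stage2.count,
            "stage2": arm.stage2.mean,
            "mle": mle(ranked, rank).estimate,
            "umvcue_known": umvcue_known(
                ranked, rank, math.sqrt(pooled_variance(ranked, rank))).estimate,
            "umvcue_unknown": umvcue_unknown(ranked, rank).estimate,
        })
    df = pd.DataFrame(rows)
    df["seed"] = seed
    return df
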