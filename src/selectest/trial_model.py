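"""Data model for two-stage selection trials.

A trial tests ``k`` experimental arms in stage 1; after an interim look the
best-ranking arms (by stage-1 sample mean, or optionally by a one-sided
z-statistic) continue into an independent stage-2 sample.  Estimation of the
selected arms' means must condition on the ordering event

    Q = {X̄_1 > X̄_2 > ... > X̄_k}

which is realised here as a relabelling: :func:`rank_and_relabel` produces a
:class:`RankedTrial` that maps ranks (1 = best) back to the original arms
without mutating the underlying data.

Summaries are stored as (count, mean, sum of squared deviations); carrying
sums of squares rather than SDs keeps reconstruction of raw second moments
exact.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidTrialError, TieWarning

RANKING_RULES = ("sample-mean", "p-value")


@dataclass(frozen=True)
class ArmStageSummary:
    """Per-arm, per-stage sufficient summary of a normal sample.

    Parameters
    ----------
    count : int
        Number of subjects (>= 1).
    mean : float
        Sample mean, in outcome units.
    ss_within : float
        Sum of squared deviations from the sample mean, in outcome units
        squared.  Zero whenever ``count == 1``.
    """

    count: int
    mean: float
    ss_within: float = 0.0

    def __post_init__(self) -> None:
        if self.count < 1:
            raise InvalidTrialError(f"count must be >= 1, got {self.count}")
        if self.ss_within < 0:
            raise InvalidTrialError(f"ss_within must be >= 0, got {self.ss_within}")
        if self.count == 1 and self.ss_within != 0:
            raise InvalidTrialError("ss_within must be 0 for a single observation")

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "ArmStageSummary":
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise InvalidTrialError("values must be a nonempty 1-d sequence")
        mean = float(arr.mean())
        ss = float(((arr - mean) ** 2).sum()) if arr.size > 1 else 0.0
        return cls(count=int(arr.size), mean=mean, ss_within=ss)

    @property
    def sum_sq(self) -> float:
        """Raw second moment contribution: sum of squared observations."""
        return self.ss_within + self.count * self.mean**2


@dataclass(frozen=True)
class Arm:
    """One experimental arm: stage-1 summary, optional stage-2 summary,
    and optional raw per-stage value vectors."""

    label: str
    stage1: ArmStageSummary
    stage2: Optional[ArmStageSummary] = None
    raw_stage1: Optional[tuple[float, ...]] = None
    raw_stage2: Optional[tuple[float, ...]] = None


@dataclass(frozen=True)
class TwoStageTrial:
    """An ordered collection of arms; stage-2 present only for continued arms."""

    arms: tuple[Arm, ...]

    def __post_init__(self) -> None:
        if len(self.arms) < 2:
            raise InvalidTrialError("a trial needs at least 2 arms")

    @property
    def k(self) -> int:
        return len(self.arms)

    @property
    def n_total(self) -> int:
        """Total stage-1 sample size N = sum of n_i."""
        return sum(a.stage1.count for a in self.arms)

    def stage1_means(self) -> np.ndarray:
        return np.array([a.stage1.mean for a in self.arms])

    def stage1_counts(self) -> np.ndarray:
        return np.array([a.stage1.count for a in self.arms])


def _arm_from_values(label: str, stage1: Sequence[float],
                     stage2: Optional[Sequence[float]] = None) -> Arm:
    s1 = ArmStageSummary.from_values(stage1)
    s2 = ArmStageSummary.from_values(stage2) if stage2 is not None else None
    return Arm(label=label, stage1=s1, stage2=s2,
               raw_stage1=tuple(float(v) for v in stage1),
               raw_stage2=tuple(float(v) for v in stage2) if stage2 is not None else None)


def trial_from_values(stage1: Sequence[Sequence[float]],
                      stage2: Optional[dict] = None,
                      labels: Optional[Sequence[str]] = None) -> TwoStageTrial:
    """Convenience constructor from raw value lists.

    ``stage2`` maps arm index (0-based, in the order of ``stage1``) to that
    arm's stage-2 values.
    """
    stage2 = stage2 or {}
    if labels is None:
        labels = [f"arm{i + 1}" for i in range(len(stage1))]
    arms = tuple(
        _arm_from_values(labels[i], vals, stage2.get(i))
        for i, vals in enumerate(stage1)
    )
    return TwoStageTrial(arms=arms)


def ranking_statistic(arm: Arm, rule: str) -> float:
    """Stage-1 ranking statistic: the sample mean, or sqrt(n)*mean for the
    one-sided z-statistic ('p-value') rule."""
    if rule == "sample-mean":
        return arm.stage1.mean
    if rule == "p-value":
        return math.sqrt(arm.stage1.count) * arm.stage1.mean
    raise InvalidTrialError(f"unknown ranking rule {rule!r}")


@dataclass(frozen=True)
class RankedTrial:
    """A trial together with the permutation realising the ordering event Q.

    ``order[r-1]`` is the index (into ``trial.arms``) of the arm at rank ``r``;
    rank 1 carries the largest ranking statistic.
    """

    trial: TwoStageTrial
    order: tuple[int, ...]
    rule: str = "sample-mean"

    def __post_init__(self) -> None:
        if sorted(self.order) != list(range(self.trial.k)):
            raise InvalidTrialError("order must be a permutation of arm indices")

    @property
    def k(self) -> int:
        return self.trial.k

    @property
    def n_total(self) -> int:
        return self.trial.n_total

    def arm(self, rank: int) -> Arm:
        """The arm occupying 1-based rank ``rank``."""
        if not 1 <= rank <= self.k:
            raise InvalidTrialError(f"rank must be in 1..{self.k}, got {rank}")
        return self.trial.arms[self.order[rank - 1]]

    def stage1_mean(self, rank: int) -> float:
        return self.arm(rank).stage1.mean

    def stage1_count(self, rank: int) -> int:
        return self.arm(rank).stage1.count

    def relabelled(self) -> TwoStageTrial:
        """A new trial with arms physically reordered by rank."""
        return TwoStageTrial(arms=tuple(self.trial.arms[i] for i in self.order))


def rank_and_relabel(trial: TwoStageTrial, rule: str = "sample-mean") -> RankedTrial:
    """Rank arms by decreasing stage-1 ranking statistic.

    Exact ties (probability zero for continuous outcomes) are broken by
    original arm order, with a :class:`TieWarning`, so simulation loops stay
    robust at degenerate settings.
    """
    if rule not in RANKING_RULES:
        raise InvalidTrialError(f"unknown ranking rule {rule!r}")
    stats = [ranking_statistic(a, rule) for a in trial.arms]
    order = tuple(sorted(range(trial.k), key=lambda i: (-stats[i], i)))
    if len(set(stats)) < len(stats):
        warnings.warn("exact ties in stage-1 ranking statistics; broken by arm order",
                      TieWarning, stacklevel=2)
    return RankedTrial(trial=trial, order=order, rule=rule)


def validate(trial: TwoStageTrial) -> list[str]:
    """Check well-formedness; returns human-readable findings (not exceptions)."""
    findings: list[str] = []
    k = trial.k
    if trial.n_total <= k:
        findings.append(f"N−k must be ≥ 1 for c>0 (N={trial.n_total}, k={k})")
    for arm in trial.arms:
        for stage_no, s in ((1, arm.stage1), (2, arm.stage2)):
            if s is None:
                continue
            if s.ss_within < 0:
                findings.append(f"arm {arm.label} stage {stage_no}: negative sum of squares")
            if not math.isfinite(s.mean):
                findings.append(f"arm {arm.label} stage {stage_no}: non-finite mean")
            if s.count > 1 and s.ss_within == 0:
                # legal (identical values) but worth surfacing for scale estimation
                pass
            raw = arm.raw_stage1 if stage_no == 1 else arm.raw_stage2
            if raw is not None:
                check = ArmStageSummary.from_values(raw)
                if (check.count != s.count
                        or not math.isclose(check.mean, s.mean, rel_tol=1e-9, abs_tol=1e-12)
                        or not math.isclose(check.ss_within, s.ss_within, rel_tol=1e-9, abs_tol=1e-9)):
                    findings.append(f"arm {arm.label} stage {stage_no}: summary disagrees with raw values")
    return findings


# ---------------------------------------------------------------------------
# CSV I/O.  Two dialects:
#   long:    arm,stage,value          (one row per observation)
#   summary: arm,n1,mean1,ss1,n2,mean2,ss2   (stage-2 cells may be empty)

_SUMMARY_COLS = ["arm", "n1", "mean1", "ss1", "n2", "mean2", "ss2"]


def read_trial_csv(path, dialect: str = "long") -> TwoStageTrial:
    """Read a trial from CSV in either dialect. Arm order follows first
    appearance (long) or row order (summary)."""
    if dialect == "long":
        df = pd.read_csv(path, dtype={"arm": str})
        for col in ("arm", "stage", "value"):
            if col not in df.columns:
                raise InvalidTrialError(f"long dialect requires column {col!r}")
        if not df["stage"].isin([1, 2]).all():
            bad = sorted(set(df["stage"]) - {1, 2})
            raise InvalidTrialError(f"unknown stage code(s) {bad}")
        values = pd.to_numeric(df["value"], errors="coerce")
        if values.isna().any():
            raise InvalidTrialError("non-numeric value in long-dialect CSV")
        df = df.assign(value=values)
        arms = []
        for label in df["arm"].drop_duplicates():
            sub = df[df["arm"] == label]
            s1 = sub.loc[sub["stage"] == 1, "value"].to_numpy()
            s2 = sub.loc[sub["stage"] == 2, "value"].to_numpy()
            if s1.size == 0:
                raise InvalidTrialError(f"arm {label} has stage-2 data but no stage-1 data")
            arms.append(_arm_from_values(str(label), s1, s2 if s2.size else None))
        return TwoStageTrial(arms=tuple(arms))
    if dialect == "summary":
        df = pd.read_csv(path, dtype={"arm": str})
        for col in _SUMMARY_COLS:
            if col not in df.columns:
                raise InvalidTrialError(f"summary dialect requires column {col!r}")
        if df["arm"].duplicated().any():
            raise InvalidTrialError("duplicate arm in summary dialect")
        arms = []
        for _, row in df.iterrows():
            s1 = ArmStageSummary(count=int(row["n1"]), mean=float(row["mean1"]),
                                 ss_within=float(row["ss1"]))
            s2 = None
            if pd.notna(row["n2"]):
                s2 = ArmStageSummary(count=int(row["n2"]), mean=float(row["mean2"]),
                                     ss_within=float(row["ss2"]))
            arms.append(Arm(label=str(row["arm"]), stage1=s1, stage2=s2))
        return TwoStageTrial(arms=tuple(arms))
    raise InvalidTrialError(f"unknown dialect {dialect!r}")


def write_trial_csv(trial: TwoStageTrial, path, dialect: str = "summary") -> None:
    """Write a trial to CSV.  The long dialect requires raw values."""
    if dialect == "long":
        rows = []
        for arm in trial.arms:
            if arm.raw_stage1 is None:
                raise InvalidTrialError(f"arm {arm.label}: raw values needed for long dialect")
            rows += [(arm.label, 1, v) for v in arm.raw_stage1]
            if arm.stage2 is not None:
                if arm.raw_stage2 is None:
                    raise InvalidTrialError(f"arm {arm.label}: raw stage-2 values needed")
                rows += [(arm.label, 2, v) for v in arm.raw_stage2]
        pd.DataFrame(rows, columns=["arm", "stage", "value"]).to_csv(
            path, index=False, float_format="%.17g")
        return
    if dialect == "summary":
        rows = []
        for arm in trial.arms:
            s1, s2 = arm.stage1, arm.stage2
            rows.append({
                "arm": arm.label, "n1": s1.count, "mean1": s1.mean, "ss1": s1.ss_within,
                "n2": s2.count if s2 else None,
                "mean2": s2.mean if s2 else None,
                "ss2": s2.ss_within if s2 else None,
            })
        pd.DataFrame(rows, columns=_SUMMARY_COLS).to_csv(
            path, index=False, float_format="%.17g")
        return
    raise InvalidTrialError(f"unknown dialect {dialect!r}")


@dataclass(frozen=True)
class EstimatorResult:
    """A point estimate for the mean of the arm at a given rank, with the
    intermediate quantities of the formula that produced it."""

    rank: int
    estimator: str
    estimate: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isfinite(self.estimate):
            raise InvalidTrialError(
                f"{self.estimator} produced non-finite estimate at rank {self.rank}")
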