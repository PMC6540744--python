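"""Hypothesis test and power-targeted sample-size rule for the two-stage design.

The end-of-trial test of H0: μ_1 <= 0 for the selected arm uses the
t-statistic T_d = Z_1 / (σ̂ sqrt(n_1 + m_1)) with σ̂² the pooled sample
variance of all stage-1 data and the rank-1 stage-2 sample; under H0 it is
treated as t-distributed on d = N + m_1 − k − 1 degrees of freedom.

To target power 1−β against a λ-standard-deviation shift the design rule
requires

    n_1 + m_1 >= (1/λ) [t⁻¹_d(1−α) + t⁻¹_d(1−β)]²

and, with a common per-group per-stage size M (n_i = m_1 = M, N = kM,
d = M(k+1) − k − 1), the smallest such M is found by an ascending scan.

Note the rule carries a 1/λ factor, not 1/λ²; this is the form the design
anchors in this package's reference studies are built on (λ = 0.5, k = 3
giving M = 4 at 50% power through M = 12 at 95%), and it is implemented
exactly as stated.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats as sp_stats

from .errors import DegenerateDataError, NonConvergenceError
from .estimators import pooled_variance
from .trial_model import RankedTrial


@dataclass(frozen=True)
class PowerSpec:
    """Design inputs: one-sided level α, type-II error β, effect size λ in
    estimated-SD multiples, and the number of arms k."""

    alpha: float
    beta: float
    lam: float
    k: int

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.beta < 1):
            raise ValueError("alpha and beta must lie in (0, 1)")
        if self.alpha + self.beta >= 1:
            raise ValueError("alpha + beta must be < 1")
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    critical: float
    reject: bool


def t_test(ranked: RankedTrial, alpha: float) -> TestResult:
    """One-sided t-test of H0: μ_1 <= 0 for the rank-1 arm."""
    arm = ranked.arm(1)
    n1 = arm.stage1.count
    m1 = arm.stage2.count if arm.stage2 is not None else 0
    sigma2_hat = pooled_variance(ranked, 1)
    if sigma2_hat <= 0:
        raise DegenerateDataError("pooled variance is zero; t-statistic undefined")
    z1 = n1 * arm.stage1.mean + m1 * arm.stage2.mean
    statistic = z1 / (math.sqrt(sigma2_hat) * math.sqrt(n1 + m1))
    df = ranked.n_total + m1 - ranked.k - 1
    critical = float(sp_stats.t.ppf(1.0 - alpha, df))
    return TestResult(statistic=statistic, df=df, critical=critical,
                      reject=statistic > critical)


def required_total(spec: PowerSpec, df: int) -> float:
    """Right-hand side of the design rule: the minimum n_1 + m_1 at the given
    degrees of freedom."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    t_a = float(sp_stats.t.ppf(1.0 - spec.alpha, df))
    t_b = float(sp_stats.t.ppf(1.0 - spec.beta, df))
    return (t_a + t_b) ** 2 / spec.lam


def min_per_group_size(spec: PowerSpec, cap: int = 10**6) -> int:
    """Smallest integer per-group per-stage size M with 2M >= required_total
    at d = M(k+1) − k − 1, by ascending scan from M = 2."""
    for m in range(2, cap + 1):
        df = m * (spec.k + 1) - spec.k - 1
        if df < 1:
            continue
        if 2 * m >= required_total(spec, df):
            return m
    raise NonConvergenceError(f"no M <= {cap} satisfies the design rule")


def sigma_hat_sampling_variance(sigma2: float, df: int) -> float:
    """Sampling variance of the pooled variance estimator: σ̂² is σ²/d times
    a chi-square on d degrees of freedom, so var(σ̂²) = 2σ⁴/d."""
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be > 0, got {sigma2}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return 2.0 * sigma2**2 / df
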