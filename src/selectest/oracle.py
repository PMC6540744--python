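"""Independent verification machinery for the Rao–Blackwell estimators.

The conditional law of the ancillary contrast U_l given the sufficient
statistic and the ordering event has density proportional to (1−u²)^{c−1}
on the clipped interval (q̲, r̲).  This module evaluates its mean by adaptive
quadrature — deliberately *not* by the closed form used in
:mod:`selectest.estimators` — so the two routes can check one another, and so
the estimator has a fallback when the closed-form Beta cdf difference
underflows.

The quadrature substitutes v = (1+u)/2, mapping the kernel to a Beta(c, c)
weight on (0, 1); this removes the endpoint singularities for c < 1.  The
integrand is scaled by its maximum log-weight on the interval so that
intervals far in the tails do not underflow.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy import integrate, stats

from .errors import DegenerateIntervalWarning
from .trial_model import RankedTrial


@dataclass(frozen=True)
class ConditionalKernel:
    """Density ∝ (1−u²)^{c−1} on (lower, upper) ⊂ [−1, 1], zero outside."""

    c: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (-1.0 <= self.lower < self.upper <= 1.0):
            raise ValueError(f"need -1 <= lower < upper <= 1, got "
                             f"({self.lower}, {self.upper})")
        if self.c <= 0:
            raise ValueError(f"need c > 0, got {self.c}")


def conditional_mean_u(kernel: ConditionalKernel) -> float:
    """E[U] under the truncated kernel, by adaptive quadrature.

    Intervals shorter than 1e-14 are degenerate at quadrature resolution:
    the midpoint is returned with a :class:`DegenerateIntervalWarning`.
    """
    c, q, r = kernel.c, kernel.lower, kernel.upper
    if r - q < 1e-14:
        warnings.warn("conditioning interval below quadrature resolution; "
                      "returning midpoint", DegenerateIntervalWarning, stacklevel=2)
        return 0.5 * (q + r)
    vq, vr = (q + 1.0) / 2.0, (r + 1.0) / 2.0

    def log_w(v: float) -> float:
        if v <= 0.0 or v >= 1.0:
            return -math.inf
        return (c - 1.0) * (math.log(v) + math.log1p(-v))

    # scale by the max log-weight: at an endpoint, or at 1/2 if interior (c>1)
    candidates = [log_w(vq), log_w(vr)]
    if vq < 0.5 < vr:
        candidates.append(log_w(0.5))
    if c < 1.0:
        # weight diverges at the endpoints; scale by the interior minimum instead
        scale = min(x for x in candidates if math.isfinite(x))
    else:
        scale = max(x for x in candidates if math.isfinite(x))

    def f0(v: float) -> float:
        lw = log_w(v) - scale
        return math.exp(lw) if lw < 700 else math.exp(700)

    def f1(v: float) -> float:
        return (2.0 * v - 1.0) * f0(v)

    pts = [0.5] if vq < 0.5 < vr else None
    with warnings.catch_warnings():
        # round-off chatter near machine precision; accuracy is enforced by
        # the closed-form agreement checks, not by QUADPACK's own estimate
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        i0, _ = integrate.quad(f0, vq, vr, epsabs=0.0, epsrel=1e-12, limit=500, points=pts)
        i1, _ = integrate.quad(f1, vq, vr, epsabs=1e-300, epsrel=1e-12, limit=500, points=pts)
    mean = i1 / i0
    # clamp to the open interval against quadrature round-off at the ends
    return min(max(mean, q), r)


def umvcue_via_quadrature(ranked: RankedTrial, l: int) -> float:
    """Reconstruct E[Ȳ_l | Z_l, X̄_c, S²_l, Q] by quadrature of the
    conditional kernel — the oracle route for the unknown-variance UMVCUE,
    and the runtime fallback on closed-form underflow."""
    from .estimators import _correction_prefactor, sufficient_statistics

    st = sufficient_statistics(ranked, l)
    eu = conditional_mean_u(ConditionalKernel(c=st.c, lower=st.q_clipped,
                                              upper=st.r_clipped))
    return st.mle + _correction_prefactor(st.n, st.m) * st.S_tilde * eu


@dataclass(frozen=True)
class UnbiasednessReport:
    """Per (estimator, rank) selection-conditional bias with its MC error."""

    rows: tuple  # of dicts: estimator, rank, bias, mc_se, passed
    n_reps: int
    seed: int

    def passed(self, estimator: str) -> bool:
        """True when |bias| <= 3 MC SE for every evaluated rank."""
        return all(r["passed"] for r in self.rows if r["estimator"] == estimator)

    def render(self) -> str:
        lines = [f"conditional-unbiasedness check ({self.n_reps} reps, seed {self.seed})"]
        for r in self.rows:
            verdict = "PASS" if r["passed"] else "FAIL"
            lines.append(f"  {r['estimator']:>16s} rank {r['rank']}: "
                         f"bias {r['bias']:+.5f} ± {r['mc_se']:.5f}  {verdict}")
        return "\n".join(lines)


def check_conditional_unbiasedness(scenario, estimator: Union[str, Sequence[str]],
                                   n_reps: int, seed: int) -> UnbiasednessReport:
    """Monte-Carlo check that an estimator's selection-conditional bias is
    statistically zero (|bias| within 3 MC standard errors).

    ``estimator`` may be a single tag or a sequence; all tags share one
    simulated data stream.
    """
    from dataclasses import replace

    from .simulation import evaluate_estimators

    tags = [estimator] if isinstance(estimator, str) else list(estimator)
    scen = replace(scenario, n_reps=n_reps, seed=seed)
    result = evaluate_estimators(scen, tags)
    rows = []
    for (tag, rank), cell in sorted(result.table.items()):
        rows.append({"estimator": tag, "rank": rank, "bias": cell["bias"],
                     "mc_se": cell["mc_se_bias"],
                     "passed": abs(cell["bias"]) <= 3.0 * cell["mc_se_bias"]})
    return UnbiasednessReport(rows=tuple(rows), n_reps=n_reps, seed=seed)


@dataclass(frozen=True)
class LawCheckSummary:
    """Kolmogorov–Smirnov comparison of simulated U*² draws to a Beta law."""

    distance: float
    threshold: float
    n_samples: int
    reference: tuple[float, float]

    @property
    def passed(self) -> bool:
        return self.distance < self.threshold


def beta_half_c_law_check(c: float, n_samples: int, seed: int,
                          reference: tuple[float, float] | None = None) -> LawCheckSummary:
    """Verify by simulation that the squared ancillary contrast U*² follows
    Beta(1/2, c) under the *unconditioned* sampling model.

    U*² is the ratio of one squared standard-normal contrast to itself plus
    an independent chi-square residual on 2c degrees of freedom.  The
    empirical cdf of n_samples draws is compared to the reference Beta cdf
    (Beta(1/2, c) unless overridden for a negative control) by KS distance;
    PASS when distance < 1.63/sqrt(n_samples), the asymptotic 1% critical
    value.
    """
    if c <= 0:
        raise ValueError(f"need c > 0, got {c}")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0)))
    z = rng.standard_normal(n_samples)
    ss = rng.chisquare(2.0 * c, n_samples)
    u2 = z**2 / (z**2 + ss)
    ref = reference if reference is not None else (0.5, c)
    dist = stats.kstest(u2, stats.beta(ref[0], ref[1]).cdf).statistic
    return LawCheckSummary(distance=float(dist),
                           threshold=1.63 / math.sqrt(n_samples),
                           n_samples=n_samples, reference=ref)
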