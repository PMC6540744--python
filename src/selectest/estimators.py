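"""Point estimators for the mean of a selected arm.

After ranking k normal arms by their stage-1 sample means and following the
rank-l arm with an independent stage-2 sample, the naive pooled estimate
Z_l/(n_l+m_l) is biased upward by selection.  Rao-Blackwellising the unbiased
stage-2 mean Ȳ_l against the complete sufficient statistic (Z_l, X̄_c, S²_l)
yields the uniformly minimum variance conditionally unbiased estimator
(UMVCUE):

    Z_l/(n_l+m_l) − sqrt(n_l/(m_l(n_l+m_l))) · S̃_l ·
        [(1−r̲²)^c − (1−q̲²)^c] / (2^{2c} c B(c,c) [F_β(v_r) − F_β(v_q)])

with c = (N−k)/2, F_β the Beta(c,c) cdf, v_x = (x+1)/2, and r̲, q̲ the
clipped standardised gaps to the ranking neighbours.  The known-variance
analogue replaces S̃_l by σ and the transformed-beta kernel by the standard
normal one.

All heavy special-function work is done in log space: c can exceed 100, where
(1−r̲²)^c underflows long before the correction ratio itself does.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import special, stats

from .errors import (
    DegenerateDataError,
    DegenerateIntervalError,
    InsufficientDFError,
    NoStageTwoDataError,
    WrongSpecialCaseError,
)
from .trial_model import EstimatorResult, RankedTrial

ESTIMATOR_TAGS = ("mle", "stage2", "umvcue_unknown", "umvcue_known", "umvcue_cs")

_LOG2 = math.log(2.0)


@dataclass(frozen=True)
class SufficientStatistics:
    """The complete sufficient statistic for rank l, plus derived quantities.

    Z = n_l·X̄_l + m_l·Ȳ_l;  mle = Z/(n_l+m_l);  c = (N−k)/2;
    S2 = ΣΣX²_ij + m_l·Ȳ²_l;  S_tilde = sqrt(S̃²_l);
    r_clipped/q_clipped are the clipped standardised gaps to the ranks
    immediately below/above (r_k = 1, q_1 = −1 by convention).
    """

    rank: int
    n: int
    m: int
    Z: float
    mle: float
    complement_means: tuple[float, ...]
    S2: float
    S_tilde: float
    c: float
    r_clipped: float
    q_clipped: float


def _neighbour_mean(ranked: RankedTrial, l: int, offset: int) -> Optional[float]:
    """Stage-1 mean of the rank-(l+offset) arm, on the scale the ranking rule
    compares against rank l; None past either end of the ordering."""
    j = l + offset
    if j < 1 or j > ranked.k:
        return None
    xbar = ranked.stage1_mean(j)
    if ranked.rule == "p-value":
        # one-sided z ranking compares sqrt(n_i)·X̄_i; the ordering constraint
        # on Ȳ_l then involves sqrt(n_j/n_l)·X̄_j in place of X̄_j
        xbar *= math.sqrt(ranked.stage1_count(j) / ranked.stage1_count(l))
    return xbar


def sufficient_statistics(ranked: RankedTrial, l: int) -> SufficientStatistics:
    """Compute (Z_l, X̄_c, S²_l) and the derived S̃_l, c, r̲_l, q̲_l for rank l.

    S̃² is evaluated through the stable decomposition

        S̃²_l = Σ_i Σ_j (X_ij − X̄_i)² + n_l m_l/(n_l+m_l) · (X̄_l − Ȳ_l)²

    which is algebraically identical to S² − (n_l+m_l)·mle² − Σ_{i≠l} n_i X̄²_i
    but avoids cancellation between large squares.
    """
    arm = ranked.arm(l)
    if arm.stage2 is None or arm.stage2.count < 1:
        raise NoStageTwoDataError(f"rank {l} (arm {arm.label}) has no stage-2 data")
    k, N = ranked.k, ranked.n_total
    if N <= k:
        raise InsufficientDFError(f"need N > k for c > 0 (N={N}, k={k})")
    n, m = arm.stage1.count, arm.stage2.count
    xbar, ybar = arm.stage1.mean, arm.stage2.mean
    Z = n * xbar + m * ybar
    mle = Z / (n + m)
    c = (N - k) / 2.0

    S2 = sum(a.stage1.sum_sq for a in ranked.trial.arms) + m * ybar**2
    within = sum(a.stage1.ss_within for a in ranked.trial.arms)
    s_tilde2 = within + n * m / (n + m) * (xbar - ybar) ** 2
    if s_tilde2 <= 0:
        raise DegenerateDataError("S̃² = 0: all observations identical")
    s_tilde = math.sqrt(s_tilde2)

    pref = math.sqrt(n * (n + m) / m)
    below = _neighbour_mean(ranked, l, +1)
    above = _neighbour_mean(ranked, l, -1)
    if below is None:  # l = k
        r_clip = 1.0
    else:
        r_clip = min(pref / s_tilde * (mle - below), 1.0)
    if above is None:  # l = 1
        q_clip = -1.0
    else:
        q_clip = max(pref / s_tilde * (mle - above), -1.0)

    comp = tuple(ranked.stage1_mean(j) for j in range(1, k + 1) if j != l)
    return SufficientStatistics(rank=l, n=n, m=m, Z=Z, mle=mle,
                                complement_means=comp, S2=S2,
                                S_tilde=s_tilde, c=c,
                                r_clipped=r_clip, q_clipped=q_clip)


def _beta_cdf_diff(c: float, vq: float, vr: float) -> float:
    """F_β(c,c)(vr) − F_β(c,c)(vq), evaluated on the smaller tail by the
    symmetry F(x) = 1 − F(1−x) to limit cancellation."""
    if vq >= 0.5:
        return special.betainc(c, c, 1.0 - vq) - special.betainc(c, c, 1.0 - vr)
    if vr <= 0.5:
        return special.betainc(c, c, vr) - special.betainc(c, c, vq)
    return special.betainc(c, c, vr) - special.betainc(c, c, vq)


def bias_correction_ratio(c: float, q_clipped: float, r_clipped: float) -> float:
    """The dimensionless bias-correction ratio

        [(1−r̲²)^c − (1−q̲²)^c] / (2^{2c} · c · B(c,c) · [F_β(v_r) − F_β(v_q)])

    equal to minus the conditional mean of the ancillary contrast U_l given
    the sufficient statistic and the ordering event.  Computed entirely in
    log space with the numerator's sign tracked explicitly.

    Raises
    ------
    DegenerateIntervalError
        when the Beta cdf difference underflows (below 1e-300); callers
        should fall back to direct quadrature of the conditional kernel.
    """
    if not (-1.0 <= q_clipped < r_clipped <= 1.0):
        raise ValueError(f"need -1 <= q < r <= 1, got q={q_clipped}, r={r_clipped}")
    if c <= 0:
        raise ValueError(f"need c > 0, got {c}")

    log_a = c * math.log1p(-r_clipped * r_clipped) if abs(r_clipped) < 1.0 else -math.inf
    log_b = c * math.log1p(-q_clipped * q_clipped) if abs(q_clipped) < 1.0 else -math.inf
    if log_a == -math.inf and log_b == -math.inf:
        return 0.0  # full interval (-1, 1): zero correction by symmetry

    cdf_diff = _beta_cdf_diff(c, (q_clipped + 1.0) / 2.0, (r_clipped + 1.0) / 2.0)
    if not cdf_diff > 1e-300:
        raise DegenerateIntervalError(
            f"Beta({c},{c}) cdf difference underflowed on "
            f"({q_clipped}, {r_clipped}); use the quadrature fallback")

    log_den = (2.0 * c * _LOG2 + math.log(c)
               + 2.0 * special.gammaln(c) - special.gammaln(2.0 * c)
               + math.log(cdf_diff))
    top = max(log_a, log_b)
    scaled = math.exp(log_a - top) - math.exp(log_b - top)
    if scaled == 0.0:
        return 0.0
    return math.copysign(math.exp(top + math.log(abs(scaled)) - log_den), scaled)


def _correction_prefactor(n: int, m: int) -> float:
    return math.sqrt(n / (m * (n + m)))


def umvcue_unknown(ranked: RankedTrial, l: int) -> EstimatorResult:
    """UMVCUE of the rank-l arm's mean with common *unknown* variance.

    Falls back to quadrature of the conditional kernel when the closed-form
    Beta cdf difference underflows (extreme c or near-degenerate interval).
    """
    st = sufficient_statistics(ranked, l)
    try:
        ratio = bias_correction_ratio(st.c, st.q_clipped, st.r_clipped)
        path = "closed-form"
    except DegenerateIntervalError:
        from .oracle import ConditionalKernel, conditional_mean_u

        ratio = -conditional_mean_u(
            ConditionalKernel(c=st.c, lower=st.q_clipped, upper=st.r_clipped))
        path = "quadrature-fallback"
    estimate = st.mle - _correction_prefactor(st.n, st.m) * st.S_tilde * ratio
    return EstimatorResult(
        rank=l, estimator="umvcue_unknown", estimate=estimate,
        diagnostics={"Z": st.Z, "mle": st.mle, "S2": st.S2, "S_tilde": st.S_tilde,
                     "c": st.c, "r_clipped": st.r_clipped, "q_clipped": st.q_clipped,
                     "correction_ratio": ratio, "path": path})


def umvcue_cs_equal(ranked: RankedTrial) -> EstimatorResult:
    """Corrected Cohen–Sackrowitz estimator: the equal-sample-size special
    case (all n_i = n, a single stage-2 observation on the rank-1 arm).

    Implemented independently of :func:`umvcue_unknown`, with two known
    corrections to the originally published formula applied: the complement
    sum in S̃² starts at i = 2, and the denominator carries 2^{2c}, not
    2^{c+1}.  The independent route lets the two implementations cross-check
    each other (they must agree exactly when both apply).
    """
    k = ranked.k
    ns = {ranked.stage1_count(j) for j in range(1, k + 1)}
    if len(ns) != 1:
        raise WrongSpecialCaseError("equal-sample-size estimator needs all n_i equal")
    n = ns.pop()
    arm = ranked.arm(1)
    if arm.stage2 is None or arm.stage2.count != 1:
        raise WrongSpecialCaseError("needs exactly one stage-2 observation on rank 1")
    y = arm.stage2.mean
    xbar1 = arm.stage1.mean
    c = k * (n - 1) / 2.0
    if c <= 0:
        raise InsufficientDFError("need n >= 2 for c > 0")
    Z = n * xbar1 + y
    mle = Z / (n + 1)
    S2 = sum(a.stage1.sum_sq for a in ranked.trial.arms) + y**2
    s_tilde2 = (S2 - (n + 1) * mle**2
                - n * sum(ranked.stage1_mean(j) ** 2 for j in range(2, k + 1)))
    if s_tilde2 <= 0:
        raise DegenerateDataError("S̃² <= 0: degenerate data")
    s_tilde = math.sqrt(s_tilde2)
    xbar2 = ranked.stage1_mean(2)
    if ranked.rule == "p-value":
        xbar2 *= math.sqrt(ranked.stage1_count(2) / n)
    r = math.sqrt(n * (n + 1)) / s_tilde * (mle - xbar2)
    r_clip = min(r, 1.0)

    if r_clip <= -1.0:
        raise DegenerateIntervalError("ordering violated: r <= -1")
    log_num = c * math.log1p(-r_clip * r_clip) if r_clip < 1.0 else -math.inf
    F_r = special.betainc(c, c, (r_clip + 1.0) / 2.0)
    log_den = (2.0 * c * _LOG2 + math.log(c)
               + 2.0 * special.gammaln(c) - special.gammaln(2.0 * c) + math.log(F_r))
    correction = 0.0 if log_num == -math.inf else math.exp(log_num - log_den)
    estimate = mle - math.sqrt(n / (n + 1)) * s_tilde * correction
    return EstimatorResult(
        rank=1, estimator="umvcue_cs", estimate=estimate,
        diagnostics={"Z": Z, "mle": mle, "S2": S2, "S_tilde": s_tilde, "c": c,
                     "r_clipped": r_clip, "q_clipped": -1.0})


def _normal_tail_ratio(w_lower: float, w_upper: float) -> float:
    """[φ(w_upper) − φ(w_lower)] / [Φ(w_upper) − Φ(w_lower)] with φ(±∞)=0,
    Φ(−∞)=0, Φ(+∞)=1 hard-coded.  Defers to the truncated-normal mean (whose
    tails are handled asymptotically by scipy) when the Φ difference
    underflows."""
    phi_u = 0.0 if math.isinf(w_upper) else math.exp(-0.5 * w_upper**2) / math.sqrt(2 * math.pi)
    phi_l = 0.0 if math.isinf(w_lower) else math.exp(-0.5 * w_lower**2) / math.sqrt(2 * math.pi)
    cdf_u = 1.0 if w_upper == math.inf else special.ndtr(w_upper)
    cdf_l = 0.0 if w_lower == -math.inf else special.ndtr(w_lower)
    denom = cdf_u - cdf_l
    if denom > 1e-300:
        return (phi_u - phi_l) / denom
    # Mills-ratio regime: −E[T | w_lower < T < w_upper] via truncnorm
    return -float(stats.truncnorm.mean(w_lower, w_upper))


@dataclass(frozen=True)
class KnownVarianceTerms:
    """Standardised gaps W_{l,l±1} entering the known-variance UMVCUE."""

    W_upper: float
    W_lower: float
    sigma: float


def known_variance_terms(ranked: RankedTrial, l: int, sigma: float) -> KnownVarianceTerms:
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    arm = ranked.arm(l)
    if arm.stage2 is None or arm.stage2.count < 1:
        raise NoStageTwoDataError(f"rank {l} (arm {arm.label}) has no stage-2 data")
    n, m = arm.stage1.count, arm.stage2.count
    mle = (n * arm.stage1.mean + m * arm.stage2.mean) / (n + m)
    pref = math.sqrt(n * (n + m) / m) / sigma
    below = _neighbour_mean(ranked, l, +1)
    above = _neighbour_mean(ranked, l, -1)
    w_upper = math.inf if below is None else pref * (mle - below)
    w_lower = -math.inf if above is None else pref * (mle - above)
    return KnownVarianceTerms(W_upper=w_upper, W_lower=w_lower, sigma=sigma)


def umvcue_known(ranked: RankedTrial, l: int, sigma: float) -> EstimatorResult:
    """UMVCUE of the rank-l arm's mean assuming the variance is *known* to be
    sigma² — the normal-kernel analogue of :func:`umvcue_unknown`."""
    terms = known_variance_terms(ranked, l, sigma)
    arm = ranked.arm(l)
    n, m = arm.stage1.count, arm.stage2.count
    mle = (n * arm.stage1.mean + m * arm.stage2.mean) / (n + m)
    ratio = _normal_tail_ratio(terms.W_lower, terms.W_upper)
    estimate = mle - _correction_prefactor(n, m) * sigma * ratio
    return EstimatorResult(
        rank=l, estimator="umvcue_known", estimate=estimate,
        diagnostics={"mle": mle, "W_upper": terms.W_upper, "W_lower": terms.W_lower,
                     "sigma": sigma, "tail_ratio": ratio})


def mle(ranked: RankedTrial, l: int) -> EstimatorResult:
    """Naive pooled (maximum-likelihood) estimate: the sample-size-weighted
    mean of the two stages.  With no stage-2 data this is the stage-1 mean."""
    arm = ranked.arm(l)
    n, xbar = arm.stage1.count, arm.stage1.mean
    if arm.stage2 is None:
        m, ybar = 0, 0.0
    else:
        m, ybar = arm.stage2.count, arm.stage2.mean
    estimate = (n * xbar + m * ybar) / (n + m)
    return EstimatorResult(rank=l, estimator="mle", estimate=estimate,
                           diagnostics={"Z": n * xbar + m * ybar, "n": n, "m": m})


def stage2_estimate(ranked: RankedTrial, l: int) -> EstimatorResult:
    """The stage-2 sample mean alone: unbiased (stage 2 is untouched by
    selection) but wasteful of the stage-1 data."""
    arm = ranked.arm(l)
    if arm.stage2 is None or arm.stage2.count < 1:
        raise NoStageTwoDataError(f"rank {l} (arm {arm.label}) has no stage-2 data")
    return EstimatorResult(rank=l, estimator="stage2", estimate=arm.stage2.mean,
                           diagnostics={"m": arm.stage2.count})


def pooled_variance(ranked: RankedTrial, l: int = 1) -> float:
    """Pooled sample variance of all stage-1 data plus the rank-l stage-2
    sample: within-group SS over N + m_l − k − 1 degrees of freedom.

    Stage-2 data of other continued ranks is excluded, mirroring the
    sufficient statistic used for rank-l estimation.
    """
    arm = ranked.arm(l)
    if arm.stage2 is None or arm.stage2.count < 1:
        raise NoStageTwoDataError(f"rank {l} has no stage-2 data")
    N, k, m = ranked.n_total, ranked.k, arm.stage2.count
    df = N + m - k - 1
    if df < 1:
        raise InsufficientDFError(f"pooled variance needs df >= 1, got {df}")
    ss = sum(a.stage1.ss_within for a in ranked.trial.arms) + arm.stage2.ss_within
    return ss / df
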