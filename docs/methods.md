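# Methods

## Model and estimand

Stage-1 observations `X_ij` (arm `i = 1..k`, subject `j = 1..n_i`) are
independent normals with means `μ_i` and a **common unknown variance σ²**.
At the interim the arms are ranked by their stage-1 sample means (an
optional variant ranks by the one-sided z-statistic `√n_i·X̄_i`); the
rank-`l` arm may continue into an independent stage-2 sample of size `m_l`
with mean `Ȳ_l`.  All estimation conditions on the ordering event
`Q = {X̄_1 > … > X̄_k}`, which is a relabelling of the arms, realised in the
code as a permutation (`RankedTrial.order`) so that re-ranking never
mutates data.

The estimand is `μ_l`, the mean of the arm occupying rank `l`.  Candidate
estimators:

- **MLE**: `Z_l/(n_l+m_l)`, `Z_l = n_l X̄_l + m_l Ȳ_l` — biased upward by
  selection, smallest spread;
- **stage-2 mean** `Ȳ_l` — unbiased (stage 2 postdates selection), largest
  spread;
- **UMVCUE, unknown variance** — `E[Ȳ_l | Z_l, X̄_c, S²_l, Q]`, the
  Rao–Blackwellisation of `Ȳ_l` against the complete sufficient statistic.
  The conditional law of the standardised ancillary contrast
  `U_l = √(m_l(n_l+m_l)/n_l)·(Ȳ_l − Z_l/(n_l+m_l))/S̃_l`
  has density ∝ `(1−u²)^{c−1}` truncated to `(q̲_l, r̲_l)`, with
  `c = (N−k)/2`; its mean gives the closed-form correction (unconditionally,
  `U_l²` is Beta(1/2, c), which the suite verifies by simulation and KS
  distance);
- **UMVCUE, known variance** — same structure with `σ` in place of `S̃_l`
  and the standard-normal kernel in place of the transformed beta kernel;
  the truncation bounds become `W_{l,l±1}`, with `Φ(±∞)` conventions
  hard-coded at the ends of the ranking;
- **equal-sample-size special case** — the historical form for all
  `n_i = n`, `m = 1`, `l = 1`, implemented independently from its own
  formula (with two known corrections to the originally published form:
  the complement sum starts at the runner-up, and the denominator carries
  `2^{2c}`) so it can cross-check the general estimator; the suite confirms
  agreement to 1e-12.

Boundary conventions: `q̲_1 = −1` and `r̲_k = 1` exactly; whenever
`r̲ = 1` and `q̲ = −1` simultaneously the correction vanishes and the
UMVCUE equals the MLE exactly.

## Numerical strategy

`c` grows with total sample size ((N−k)/2 ≈ 100 already for modest trials),
so `(1−r̲²)^c`, `2^{2c}` and `B(c,c)` under/overflow far before the
correction ratio does.  All factors are therefore combined in log space
(`gammaln`, `c·log1p(−x²)`) with the numerator's sign tracked explicitly.
The Beta(c,c) cdf difference is evaluated on the smaller tail via the
symmetry `F(x) = 1 − F(1−x)`.  If that difference still underflows (below
1e-300) the estimator defers to direct quadrature of the truncated kernel
rather than returning 0/0 — the quadrature path is a shipped, tested module
(`selectest.oracle`), not test-only code, precisely because it backs the
fast path at runtime.

The quadrature substitutes `v = (1+u)/2`, turning the kernel into a
Beta(c,c) weight on (0,1); this removes the endpoint singularities for
`c < 1`.  The integrand is scaled by its extremal log-weight on the
interval so tail intervals do not underflow, and the two routes
(closed form vs quadrature) are held to 1e-8 relative agreement across
`c ∈ {0.5, 1, 5, 50, 500}` in the suite.  Intervals shorter than 1e-14
return the midpoint with a warning.  The normal-kernel tail ratio similarly
falls back to scipy's truncated-normal mean (asymptotically stable in far
tails) when the Φ difference underflows.

`S̃²_l` is computed through the algebraic decomposition

    S̃²_l = Σ_i Σ_j (X_ij − X̄_i)² + n_l m_l/(n_l+m_l) · (X̄_l − Ȳ_l)²

— a sum of nonnegative terms — instead of the equivalent literal
subtraction `S²_l − (n_l+m_l)·mle² − Σ_{i≠l} n_i X̄_i²`, which cancels
catastrophically when means are far from zero.  The suite asserts both
routes agree to 1e-9 relative.  Note `S²_l` carries `m_l·Ȳ_l²` (not
`Σ_j Y²_lj`): `S̃` deliberately excludes the stage-2 within-sample sum of
squares, matching the sufficient statistic.  For the same reason,
estimation and the pooled variance for rank `l` use only that rank's
stage-2 sample even when several ranks continued.

Exact ties in the ranking statistic (probability zero for continuous data,
but reachable at σ² = 0) are broken by original arm order with a warning,
not an error, to keep simulation loops robust.

## Design solver and test

The end-of-trial test of `H0: μ_1 ≤ 0` uses
`T_d = Z_1/(σ̂ √(n_1+m_1))` with `σ̂²` the pooled sample variance of all
stage-1 data plus the rank-1 stage-2 sample, on `d = N + m_1 − k − 1`
degrees of freedom.  The sampling noise of that plug-in is
`var(σ̂²) = 2σ⁴/d` (0.0556 at σ² = 1, d = 36).

The sample-size rule requires
`n_1 + m_1 ≥ (1/λ)[t⁻¹_d(1−α) + t⁻¹_d(1−β)]²` and is solved for the common
per-group per-stage size `M` (so `d = M(k+1) − k − 1`) by an ascending
integer scan.  **The rule is implemented with the `1/λ` factor exactly as
stated**, because only that form reproduces the design anchors the
evaluation studies are built on (λ = 0.5, k = 3: M = 4 at 50% power up to
M = 12 at 95%).  The textbook normal-theory rule would carry `1/λ²`; a
consequence of the stated form is that it under-sizes as the power demand
grows — at the 95% target the realised Monte-Carlo power is ≈ 0.94 rather
than 0.95, even with the selection-induced boost from evaluating the
best-ranking arm.  The suite pins this anticonservatism explicitly rather
than hiding it.  Quantiles use the exact inverse t cdf throughout; no
normal approximation, since `d` as small as 12 matters.

The t-statistic's nominal null law holds for a *pre-specified* arm (the
ordering event is a relabelling of an exchangeable null); applied to the
selected arm the naive test inherits the MLE's selection bias.  The suite
calibrates the statistic against its stated law in the pre-specified-arm
setting and tracks the selection bias through the estimator studies.

## Simulation harness

`simulate_trial` draws each (replicate, arm, stage) sample from its own
`SeedSequence`-keyed generator, so a trial is a pure function of
(seed, replicate) and the data stream cannot shift when estimators are
added.  Selection-conditional bias and MSE are accumulated replicate-wise
as `estimate − μ_(arm at the evaluated rank)` — identical to the
selection-event-weighted definitions, without enumerating events.
Replicates in which an estimator fails are excluded and counted; more than
0.1% failures aborts the run (in practice none occur at the study
settings).

Reference study conditions (generator defaults): k = 3 arms with equal true
means 0, σ² = 1, `n_i = m_1 = M` with M from the design solver (M = 10 at
the 90% design point), rank-1 selection, 10⁵ replicates.  Scaled-down runs
in the test suite use 2×10⁴ replicates with 3-MC-SE tolerances.  The
plug-in sensitivity study fixes the data (M = 10) and varies only the
variance plugged into the known-variance estimator over 0.25–4; the
estimators that ignore the plug-in are computed once and shared across the
grid, so their rows are exactly constant by construction.

The case study emulates a small seamless dose-finding trial: three doses
with true placebo-adjusted outcome differences (0.15, 0.18, 0.21) L,
outcome SD 0.3 L, stage-1 sizes (10, 9, 7), the top two ranks continued
with 9 subjects each.  Treatment differences are modelled directly as the
normal outcome; no placebo arm is simulated, since only difference
summaries define the scenario.  The MLE column of the report equals the
weighted mean of the realised stage means exactly, and across realisations
the two bias corrections agree to well within a tenth of the
stage-1-vs-stage-2 spread.

### What the generator does and does not emulate

It emulates exactly the assumptions the estimators are derived under:
normality, a common variance across arms and stages, independence of the
two stages, and ranking by the stated statistic.  It does not emulate
non-normal outcomes, unequal per-arm variances, covariate adjustment,
early stopping, or correlation between endpoints — so passing tests
certify the estimators under their own model, not robustness beyond it.

## Known limitations

- No conditionally unbiased estimator exists for a rank without stage-2
  data (`m_l = 0` is rejected), and the approach does not extend to
  per-arm variances `σ²_i`.
- Confidence intervals are out of scope; the package does point estimation
  only.
- The p-value ranking variant interprets the ordering statistic as
  `√n_i·X̄_i` (the one-sided z-statistic); the alternative `n_i·X̄_i`
  reading is deliberately not offered.
- The known-variance estimator with a badly mis-specified plug-in is
  biased (upward for plug-ins below the truth, downward above); the
  sensitivity study quantifies this.
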