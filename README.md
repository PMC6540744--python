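# selectest

Conditionally unbiased estimation after interim treatment selection in
two-stage trials with normally distributed outcomes and a **common unknown
variance**.

## The problem

A two-stage drop-the-losers design tests `k` experimental arms in stage 1,
ranks them by their stage-1 sample means, and carries the best-ranking
arm(s) into an independent stage-2 sample.  Because an arm had to perform
well at the interim to continue, the naive pooled estimate of its mean —
the sample-size-weighted MLE `Z_l/(n_l+m_l)` with `Z_l = n_l·X̄_l + m_l·Ȳ_l`
— is biased upward.  The stage-2 mean alone is unbiased but discards the
stage-1 data.

Rao–Blackwellisation fixes both defects: conditioning the unbiased stage-2
mean `Ȳ_l` on the complete sufficient statistic `(Z_l, X̄_c, S²_l)` and on
the interim ordering event `Q = {X̄_1 > … > X̄_k}` gives the **uniformly
minimum variance conditionally unbiased estimator (UMVCUE)**

```
μ̂_l = Z_l/(n_l+m_l) − √(n_l/(m_l(n_l+m_l))) · S̃_l ·
        [(1−r̲_l²)^c − (1−q̲_l²)^c] / (2^{2c} c B(c,c) [F_β(½(r̲_l+1)) − F_β(½(q̲_l+1))])
```

where `c = (N−k)/2` with `N = Σ n_i`, `F_β` is the Beta(c,c) cdf, `S̃_l` is a
scale statistic built from the pooled sums of squares, and `r̲_l, q̲_l` are
clipped standardised gaps between the rank-`l` pooled mean and its ranking
neighbours (`q̲_1 = −1`, `r̲_k = 1` at the ends).  It handles unequal stage-1
sample sizes, any stage-2 size, and any rank `l` — not just the winner.

The package also provides:

- the **known-variance UMVCUE** (normal kernel in place of the transformed
  beta kernel), the **MLE** and the **stage-2 estimator**, for comparison;
- the corrected **equal-sample-size special case** (all `n_i = n`, one
  stage-2 observation);
- a **design solver** for the per-group per-stage size `M` meeting a
  one-sided power target, and the end-of-trial t-test;
- a **simulation harness** measuring selection-conditional bias and MSE
  (`b_sel`, `MSE_sel`) of all estimators, including the plug-in-variance
  sensitivity study and a small dose-finding case study;
- an independent **quadrature oracle** for the conditional expectation,
  used both for verification and as a runtime fallback when the closed form
  underflows.

## Worked example

The winner of a tiny two-arm trial (stage-1 values `{1, −1}` vs
`{0.9, −1.1}`, one stage-2 observation `0.0`) barely beat the runner-up:

```python
import selectest as st

trial = st.trial_from_values([[1.0, -1.0], [0.9, -1.1]], {0: [0.0]})
ranked = st.rank_and_relabel(trial)
st.mle(ranked, 1).estimate              #  0.0000
st.umvcue_unknown(ranked, 1).estimate   # -0.7165
st.umvcue_known(ranked, 1, 1.0).estimate  # -0.5297
```

The pooled MLE is 0.0, but conditional on having won by so narrow a margin
(0.0 vs −0.1) an unbiased assessment is considerably lower: −0.717 with the
variance estimated from these four noisy observations, −0.530 when the SD
is known to be 1.  See `examples/` for runnable scripts covering
estimation, design, the bias/MSE study (MLE bias ≈ +0.13 at the 90%-power
design point, UMVCUE bias ≈ 0 with MSE ≈ 0.074) and the dose-finding case
study.

## Command line

```sh
selectest power --alpha 0.05 --beta 0.1 --lambda 0.5 --k 3   # -> M = 10
selectest make-fixture --kind worked-example --out trial.csv
selectest estimate --trial trial.csv --ranks 1 --estimators all --sigma pooled
selectest simulate --preset power-grid --n-reps 10000 --seed 1 --out out/
selectest case-study --seed 7
```

Trial CSVs come in a `long` dialect (`arm,stage,value`, one row per
observation) and a `summary` dialect (`arm,n1,mean1,ss1,n2,mean2,ss2`).

## Further reading

`docs/methods.md` describes the model and its assumptions, the numerical
strategy for the special-function kernels, the simulation design, and known
limitations.
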