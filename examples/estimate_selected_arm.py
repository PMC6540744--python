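"""Estimate the mean of the winning arm of a tiny two-stage trial.

Two arms are tested in stage 1; the one with the larger sample mean gets a
single confirmatory stage-2 observation.  Because the winner had to win, the
naive pooled estimate is optimistic; the UMVCUE removes that selection bias
by conditioning the unbiased stage-2 mean on the complete sufficient
statistic.
"""
import selectest as st

# stage-1 values per arm; the first arm wins (mean 0.0 vs -0.1) and
# contributes one stage-2 observation of 0.0
trial = st.trial_from_values(
    stage1=[[1.0, -1.0], [0.9, -1.1]],
    stage2={0: [0.0]},
    labels=["A", "B"],
)
ranked = st.rank_and_relabel(trial)

print("rank 1 arm:", ranked.arm(1).label)
print(f"  stage-1 mean : {ranked.arm(1).stage1.mean:+.4f}")
print(f"  stage-2 mean : {ranked.arm(1).stage2.mean:+.4f}")
print(f"  MLE (pooled) : {st.mle(ranked, 1).estimate:+.4f}")
print(f"  UMVCUE (unknown variance): {st.umvcue_unknown(ranked, 1).estimate:+.4f}")
print(f"  UMVCUE (known sigma = 1) : {st.umvcue_known(ranked, 1, 1.0).estimate:+.4f}")

# The UMVCUEs fall below the MLE: the margin of victory over arm B was
# narrow (0.0 vs -0.1), so conditioning on having won pulls the estimate
# down.  With so little data the unknown-variance correction (-0.717) is
# stronger than the known-variance one (-0.530).
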