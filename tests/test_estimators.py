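"""Estimator formulas: hand-computed anchors, algebraic identities,
special-case consistency, and the known-variance analogue."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h
from scipy import integrate

import selectest as st
from selectest.errors import (
    DegenerateIntervalError,
    NoStageTwoDataError,
    WrongSpecialCaseError,
)
from selectest.estimators import _normal_tail_ratio, known_variance_terms
from tests.conftest import make_random_ranked


class TestSufficientStatistics:
    def test_hand_example_boundary(self, boundary_ranked):
        s = st.sufficient_statistics(boundary_ranked, 1)
        assert s.Z == 3.0
        assert s.mle == 1.0
        assert s.c == 1.0
        assert s.S2 == pytest.approx(5.0)
        assert s.S_tilde**2 == pytest.approx(2.0)
        assert s.r_clipped == 1.0   # raw r = sqrt(3) clipped
        assert s.q_clipped == -1.0  # rank-1 convention

    def test_hand_example_worked(self, worked_ranked):
        s = st.sufficient_statistics(worked_ranked, 1)
        assert s.Z == pytest.approx(0.0)
        assert s.c == 1.0
        assert s.S2 == pytest.approx(4.02)
        assert s.S_tilde == pytest.approx(2.0)
        assert s.r_clipped == pytest.approx(math.sqrt(6) * 0.05)  # 0.122474
        assert s.q_clipped == -1.0

    def test_decomposition_identity_random_trials(self):
        # S̃² from the stable decomposition equals the literal subtraction
        rng = np.random.default_rng(21)
        for _ in range(200):
            ranked = make_random_ranked(rng)
            s = st.sufficient_statistics(ranked, 1)
            direct = (s.S2 - (s.n + s.m) * s.mle**2
                      - sum(ranked.stage1_count(j) * ranked.stage1_mean(j) ** 2
                            for j in range(2, ranked.k + 1)))
            assert s.S_tilde**2 == pytest.approx(direct, rel=1e-9, abs=1e-9)
            assert s.S_tilde > 0
            assert s.q_clipped < s.r_clipped

    def test_matched_means_reduce_to_within_ss(self):
        # Ȳ = X̄ on the selected arm: between-stage term vanishes
        trial = st.trial_from_values([[1.0, 3.0], [0.0, 1.0]], {0: [2.0, 2.0]})
        ranked = st.rank_and_relabel(trial)
        s = st.sufficient_statistics(ranked, 1)
        within = sum(a.stage1.ss_within for a in trial.arms)
        assert s.S_tilde**2 == pytest.approx(within)

    def test_missing_stage2_raises(self, worked_ranked):
        with pytest.raises(NoStageTwoDataError):
            st.sufficient_statistics(worked_ranked, 2)


class TestBiasCorrectionRatio:
    def test_c1_closed_form(self):
        # c=1: Beta(1,1) cdf is the identity -> hand arithmetic
        r = math.sqrt(6) * 0.05
        got = st.bias_correction_ratio(1.0, -1.0, r)
        assert got == pytest.approx((1 - r**2) / (4 * 1.0 * ((r + 1) / 2)), rel=1e-12)
        assert got == pytest.approx(0.438763, abs=1e-6)

    def test_full_interval_is_zero(self):
        for c in (0.5, 1.0, 7.0, 250.0):
            assert st.bias_correction_ratio(c, -1.0, 1.0) == 0.0

    def test_symmetric_interval_is_zero(self):
        assert st.bias_correction_ratio(3.0, -0.5, 0.5) == 0.0

    def test_large_c_does_not_underflow(self):
        # c = 400: (1-r̲²)^c underflows but the ratio is well-scaled
        val = st.bias_correction_ratio(400.0, -0.2, -0.1)
        assert math.isfinite(val)
        assert 0.1 < val < 0.2  # ratio = -E[U] in (-r̲, -q̲)

    def test_extreme_interval_raises_degenerate(self):
        with pytest.raises(DegenerateIntervalError):
            st.bias_correction_ratio(500.0, 0.95, 0.99)

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(log_c=st_h.floats(math.log(0.2), math.log(200)),
           q=st_h.floats(-0.9, 0.8),
           gap=st_h.floats(0.05, 1.0))
    def test_ratio_bounds_and_antisymmetry(self, log_c, q, gap):
        # ratio = -E[U|q̲<U<r̲] lies strictly inside (-r̲, -q̲), and the
        # kernel's symmetry u -> -u flips its sign
        c = math.exp(log_c)
        r = min(q + gap, 0.9)
        if r - q < 0.05:
            return
        val = st.bias_correction_ratio(c, q, r)
        assert -r < val < -q
        mirrored = st.bias_correction_ratio(c, -r, -q)
        assert mirrored == pytest.approx(-val, rel=1e-9, abs=1e-12)


class TestUmvcueUnknown:
    def test_worked_example(self, worked_ranked):
        res = st.umvcue_unknown(worked_ranked, 1)
        assert res.estimate == pytest.approx(-math.sqrt(2 / 3) * 2 * 0.43876276, abs=1e-6)
        assert res.estimate == pytest.approx(-0.71650, abs=1e-5)
        for key in ("Z", "S_tilde", "c", "r_clipped", "q_clipped"):
            assert key in res.diagnostics

    def test_zero_correction_boundary_equals_mle(self, boundary_ranked):
        res = st.umvcue_unknown(boundary_ranked, 1)
        assert res.estimate == st.mle(boundary_ranked, 1).estimate == 1.0

    def test_equals_equal_size_special_case(self, boundary_ranked):
        assert st.umvcue_unknown(boundary_ranked, 1).estimate == pytest.approx(
            st.umvcue_cs_equal(boundary_ranked).estimate, abs=1e-12)

    def test_remark2_equivalence_random_trials(self):
        # equal n_i, m=1: the general estimator reduces to the corrected
        # equal-sample-size form, to 1e-12, on 100 random trials
        rng = np.random.default_rng(23)
        for _ in range(100):
            n = int(rng.integers(2, 9))
            ranked = make_random_ranked(rng, equal_n=n, m=1)
            a = st.umvcue_unknown(ranked, 1).estimate
            b = st.umvcue_cs_equal(ranked).estimate
            assert a == pytest.approx(b, rel=1e-12, abs=1e-12)

    def test_special_case_guards(self, worked_ranked):
        unequal = st.rank_and_relabel(
            st.trial_from_values([[1.0, 2.0, 3.0], [0.0, 1.0]], {0: [1.0]}))
        with pytest.raises(WrongSpecialCaseError):
            st.umvcue_cs_equal(unequal)
        multi_m = st.rank_and_relabel(
            st.trial_from_values([[1.0, 2.0], [0.0, 1.0]], {0: [1.0, 2.0]}))
        with pytest.raises(WrongSpecialCaseError):
            st.umvcue_cs_equal(multi_m)


class TestUmvcueKnown:
    def test_worked_example_sigma_one(self, worked_ranked):
        res = st.umvcue_known(worked_ranked, 1, sigma=1.0)
        w = math.sqrt(6) * 0.1
        phi = math.exp(-w**2 / 2) / math.sqrt(2 * math.pi)
        from scipy.special import ndtr
        expected = 0.0 - math.sqrt(2 / 3) * phi / ndtr(w)
        assert res.estimate == pytest.approx(expected, rel=1e-12)
        assert res.estimate == pytest.approx(-0.530, abs=5e-4)
        assert res.diagnostics["W_upper"] == pytest.approx(w)
        assert res.diagnostics["W_lower"] == -math.inf

    def test_unbounded_interval_reduces_to_mle(self):
        # rank 1 of k... with both neighbours absent the correction vanishes;
        # emulate via a 2-arm trial evaluated at both ends and the identity
        # phi(inf)=0: the tail ratio over (-inf, inf) is exactly 0
        assert _normal_tail_ratio(-math.inf, math.inf) == 0.0

    def test_matches_truncated_normal_quadrature(self):
        # independent oracle: E[T | a < T < b] by numerical integration
        rng = np.random.default_rng(24)
        for _ in range(25):
            ranked = make_random_ranked(rng)
            sigma = float(math.exp(rng.normal(0, 0.5)))
            terms = known_variance_terms(ranked, 1, sigma)
            a, b = terms.W_lower, max(terms.W_upper, terms.W_lower + 1e-6)
            lo = a if math.isfinite(a) else -40.0
            phi = lambda t: math.exp(-t * t / 2) / math.sqrt(2 * math.pi)
            num, _ = integrate.quad(lambda t: t * phi(t), lo, b)
            den, _ = integrate.quad(phi, lo, b)
            expected_ratio = -num / den
            got = st.umvcue_known(ranked, 1, sigma).diagnostics["tail_ratio"]
            assert got == pytest.approx(expected_ratio, rel=1e-6, abs=1e-9)

    def test_far_tail_uses_stable_path(self):
        # interval entirely 40+ SDs out: naive cdf difference is 0/0
        val = _normal_tail_ratio(41.0, 42.0)
        assert math.isfinite(val)
        assert -42.0 < val < -41.0

    def test_structural_convergence_to_beta_kernel(self):
        # on standardised inputs w = sqrt(2c)·u the transformed-beta
        # correction approaches the normal one as c grows
        w_lo, w_up = -0.7, 1.3
        target = _normal_tail_ratio(w_lo, w_up)
        errs = []
        for c in (1e3, 1e4):
            scale = math.sqrt(2 * c)
            got = scale * st.bias_correction_ratio(c, w_lo / scale, w_up / scale)
            errs.append(abs(got - target))  # both equal -E[standardised contrast]
        assert errs[1] < errs[0]
        assert errs[1] < 1e-3

    def test_sigma_must_be_positive(self, worked_ranked):
        with pytest.raises(ValueError):
            st.umvcue_known(worked_ranked, 1, sigma=0.0)


class TestSimpleEstimators:
    @pytest.mark.parametrize("n,xbar,m,ybar,expected", [
        (7, 0.218, 9, 0.179, 0.196),   # dose-report arithmetic, 3 d.p.
        (9, 0.192, 9, 0.180, 0.186),
    ])
    def test_mle_weighted_mean(self, n, xbar, m, ybar, expected):
        trial = st.TwoStageTrial(arms=(
            st.Arm("sel", st.ArmStageSummary(n, xbar, 0.1),
                   st.ArmStageSummary(m, ybar, 0.1)),
            st.Arm("other", st.ArmStageSummary(5, xbar - 0.1, 0.1))))
        ranked = st.rank_and_relabel(trial)
        got = st.mle(ranked, 1).estimate
        assert got == pytest.approx((n * xbar + m * ybar) / (n + m), rel=1e-15)
        assert round(got, 3) == expected

    def test_mle_identity_when_stages_agree(self):
        trial = st.trial_from_values([[0.4, 0.4], [0.0, 0.0]], {0: [0.4]})
        ranked = st.rank_and_relabel(trial)
        assert st.mle(ranked, 1).estimate == pytest.approx(0.4)

    def test_stage2_ignores_stage1(self):
        t1 = st.trial_from_values([[5.0, 7.0], [0.0, 1.0]], {0: [0.179]})
        t2 = st.trial_from_values([[50.0, 70.0], [0.0, 1.0]], {0: [0.179]})
        for t in (t1, t2):
            assert st.stage2_estimate(st.rank_and_relabel(t), 1).estimate == 0.179

    def test_stage2_requires_data(self, worked_ranked):
        with pytest.raises(NoStageTwoDataError):
            st.stage2_estimate(worked_ranked, 2)


class TestPooledVariance:
    def test_hand_example(self):
        # k=2, n=(2,2), stage-1 SS (2, 0.02), m=1 (SS 0): 2.02/2 = 1.01
        ranked = st.rank_and_relabel(
            st.trial_from_values([[1.0, -1.0], [0.0, -0.2]], {0: [0.5]}))
        assert st.pooled_variance(ranked, 1) == pytest.approx(2.02 / 2)

    def test_identical_values_give_zero(self):
        ranked = st.rank_and_relabel(
            st.trial_from_values([[1.0, 1.0], [0.0, 0.0]], {0: [1.0, 1.0]}))
        assert st.pooled_variance(ranked, 1) == 0.0

    def test_raw_equals_summary_representation(self, tmp_path):
        rng = np.random.default_rng(25)
        ranked = make_random_ranked(rng)
        p = tmp_path / "s.csv"
        st.write_trial_csv(ranked.trial, p, "summary")
        back = st.rank_and_relabel(st.read_trial_csv(p, "summary"))
        assert st.pooled_variance(back, 1) == pytest.approx(
            st.pooled_variance(ranked, 1), rel=1e-12)
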