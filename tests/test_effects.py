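"""Effect-measure construction: values against hand-evaluated formulas,
antisymmetry, large-sample behaviour and sampling calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from knee_nma.data import Trial
from knee_nma.effects import (
    DegenerateArmError,
    hedges_g,
    log_odds_ratio,
    mean_difference,
    trial_contrasts,
)

from conftest import binary_arm, continuous_arm, jsw_arm


class TestHedgesG:
    def test_identical_arms_give_zero(self):
        a = continuous_arm("T", "placebo", mean=-1.0)
        b = continuous_arm("T", "glucosamine", mean=-1.0)
        g = hedges_g(a, b)
        assert g.estimate == 0.0
        assert g.variance == pytest.approx((100 + 100) / (100 * 100))

    def test_hand_evaluated_example(self):
        # means -1.0 vs -2.0, common SD 2.5, n = 100 per arm:
        # d = -0.4, J = 1 - 3/791, g = J * d
        a = continuous_arm("T", "placebo", mean=-1.0, sd=2.5)
        b = continuous_arm("T", "celecoxib", mean=-2.0, sd=2.5)
        g = hedges_g(a, b)
        j = 1.0 - 3.0 / (4.0 * 198 - 1.0)
        assert g.estimate == pytest.approx(-0.4 * j, abs=1e-12)
        assert g.estimate == pytest.approx(-0.3985, abs=5e-4)
        assert g.variance == pytest.approx(0.02 + g.estimate**2 / 400.0, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        a = continuous_arm("T", "placebo", sd=1.0)
        with pytest.raises(DegenerateArmError, match="n >= 2"):
            hedges_g(a, continuous_arm("T", "celecoxib", n=1))
        zero = continuous_arm("T", "celecoxib", sd=1e-300)
        az = continuous_arm("T", "placebo", sd=1e-300)
        with pytest.raises(DegenerateArmError, match="pooled SD"):
            hedges_g(az, zero)

    def test_converges_to_cohens_d_for_large_n(self):
        n = 10**6
        a = continuous_arm("T", "placebo", n=n, mean=0.0, sd=1.0)
        b = continuous_arm("T", "celecoxib", n=n, mean=-0.5, sd=1.0)
        g = hedges_g(a, b)
        assert abs(g.estimate - (-0.5)) < 1e-5


class TestMeanDifference:
    def test_equal_arms_and_sign_convention(self):
        a = jsw_arm("T", "placebo", narrowing=0.3)
        b = jsw_arm("T", "glucosamine", narrowing=0.3)
        assert mean_difference(a, b).estimate == 0.0
        # treatment narrows 0.10 mm vs placebo 0.40 mm: MD +0.30 (joint space preserved)
        a = jsw_arm("T", "placebo", narrowing=0.40, sd=0.5, n=50)
        b = jsw_arm("T", "glucosamine", narrowing=0.10, sd=0.5, n=50)
        md = mean_difference(a, b)
        assert md.estimate == pytest.approx(0.30)
        assert md.variance == pytest.approx(0.25 / 50 + 0.25 / 50)

    def test_mixed_outcome_types_rejected(self):
        with pytest.raises(DegenerateArmError):
            mean_difference(jsw_arm("T", "placebo"), continuous_arm("T", "celecoxib"))

    def test_simulation_recovers_truth(self):
        """Mean of MD estimates over replicates within 3 MC SDs of 0.18 mm."""
        rng = np.random.default_rng(11)
        truth, sd, n = 0.18, 0.45, 80
        reps = 500
        ests = np.empty(reps)
        for r in range(reps):
            base = rng.normal(0.30, sd / math.sqrt(n))
            treat = rng.normal(0.30 - truth, sd / math.sqrt(n))
            a = jsw_arm("T", "placebo", n=n, narrowing=base, sd=sd)
            b = jsw_arm("T", "glucosamine", n=n, narrowing=treat, sd=sd)
            ests[r] = mean_difference(a, b).estimate
        mc_se = ests.std(ddof=1) / math.sqrt(reps)
        assert abs(ests.mean() - truth) < 3 * mc_se


class TestLogOddsRatio:
    def test_hand_evaluated_example(self):
        a = binary_arm("T", "placebo", n=20, events=5)
        b = binary_arm("T", "celecoxib", n=20, events=10)
        lor = log_odds_ratio(a, b)
        assert lor.estimate == pytest.approx(math.log(3.0))
        assert lor.variance == pytest.approx(1 / 10 + 1 / 10 + 1 / 5 + 1 / 15)

    def test_continuity_correction_single_zero(self):
        # 0/20 vs 5/20 -> +0.5 everywhere: OR = (5.5 * 20.5) / (0.5 * 15.5)
        a = binary_arm("T", "placebo", n=20, events=0)
        b = binary_arm("T", "celecoxib", n=20, events=5)
        lor = log_odds_ratio(a, b)
        assert lor.estimate == pytest.approx(math.log((5.5 * 20.5) / (0.5 * 15.5)))
        assert lor.informative

    def test_double_zero_flagged_non_informative(self):
        a = binary_arm("T", "placebo", n=20, events=0)
        b = binary_arm("T", "celecoxib", n=20, events=0)
        assert not log_odds_ratio(a, b).informative

    def test_equal_risks_give_zero(self):
        a = binary_arm("T", "placebo", n=40, events=8)
        b = binary_arm("T", "celecoxib", n=20, events=4)
        assert log_odds_ratio(a, b).estimate == pytest.approx(0.0)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    ma=st.floats(-3, 3),
    mb=st.floats(-3, 3),
    sa=st.floats(0.5, 4),
    sb=st.floats(0.5, 4),
    na=st.integers(5, 500),
    nb=st.integers(5, 500),
)
def test_antisymmetry_under_arm_swap(ma, mb, sa, sb, na, nb):
    a = continuous_arm("T", "placebo", n=na, mean=ma, sd=sa)
    b = continuous_arm("T", "celecoxib", n=nb, mean=mb, sd=sb)
    fwd, rev = hedges_g(a, b), hedges_g(b, a)
    assert fwd.estimate == pytest.approx(-rev.estimate, abs=1e-12)
    assert fwd.variance == pytest.approx(rev.variance, abs=1e-12)

    aj = jsw_arm("T", "placebo", n=na, narrowing=ma, sd=sa)
    bj = jsw_arm("T", "celecoxib", n=nb, narrowing=mb, sd=sb)
    assert mean_difference(aj, bj).estimate == -mean_difference(bj, aj).estimate


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    ea=st.integers(1, 19),
    eb=st.integers(1, 19),
)
def test_log_or_antisymmetry(ea, eb):
    a = binary_arm("T", "placebo", n=20, events=ea)
    b = binary_arm("T", "celecoxib", n=20, events=eb)
    fwd, rev = log_odds_ratio(a, b), log_odds_ratio(b, a)
    assert fwd.estimate == pytest.approx(-rev.estimate)
    assert fwd.variance == pytest.approx(rev.variance)


class TestTrialContrasts:
    def test_two_arm_covariance_is_the_variance(self):
        t = Trial("T", (continuous_arm("T", "placebo"), continuous_arm("T", "celecoxib", mean=-2.0)))
        tc = trial_contrasts(t, "smd")
        assert tc.covariance.shape == (1, 1)
        assert tc.covariance[0, 0] == pytest.approx(tc.contrasts[0].variance)

    def test_three_arm_shared_baseline_covariance(self):
        t = Trial(
            "T",
            (
                continuous_arm("T", "placebo"),
                continuous_arm("T", "glucosamine", mean=-1.3),
                continuous_arm("T", "celecoxib", mean=-1.7),
            ),
        )
        tc = trial_contrasts(t, "smd")
        assert tc.covariance[0, 1] == pytest.approx(1.0 / 100)

    def test_four_arm_covariance_matches_resimulation(self):
        """Analytic covariance vs the empirical covariance of contrast
        estimates over 10,000 resimulated four-arm trials (truth: no effect)."""
        rng = np.random.default_rng(5)
        n, sd = 100, 2.0
        reps = 10_000
        means = rng.normal(-1.0, sd / math.sqrt(n), size=(reps, 4))
        sds = sd * np.sqrt(rng.chisquare(n - 1, size=(reps, 4)) / (n - 1))
        ests = np.empty((reps, 3))
        treatments = ["placebo", "glucosamine", "chondroitin", "celecoxib"]
        analytic = None
        for r in range(reps):
            arms = tuple(
                continuous_arm("T", t, n=n, mean=means[r, j], sd=sds[r, j])
                for j, t in enumerate(treatments)
            )
            tc = trial_contrasts(Trial("T", arms), "smd")
            ests[r] = tc.estimates
            if r == 0:
                analytic = tc.covariance
        emp = np.cov(ests.T)
        assert np.all(np.linalg.eigvalsh(analytic) > 0)
        # diagonal ~ 0.02, off-diagonal ~ 0.01 at n = 100 and zero effect
        assert np.allclose(emp, analytic, rtol=0.10, atol=0.002)


def test_estimator_calibration_two_arm_smd():
    """Over 5,000 simulated trials at a fixed truth the mean estimate is
    within 3 MC SDs and the mean variance estimate within 10% of the
    empirical variance."""
    rng = np.random.default_rng(17)
    n, sd, truth = 50, 2.5, -0.3
    reps = 5_000
    ests = np.empty(reps)
    variances = np.empty(reps)
    for r in range(reps):
        ma = rng.normal(-1.0, sd / math.sqrt(n))
        mb = rng.normal(-1.0 + truth * sd, sd / math.sqrt(n))
        sa = sd * math.sqrt(rng.chisquare(n - 1) / (n - 1))
        sb = sd * math.sqrt(rng.chisquare(n - 1) / (n - 1))
        c = hedges_g(
            continuous_arm("T", "placebo", n=n, mean=ma, sd=sa),
            continuous_arm("T", "celecoxib", n=n, mean=mb, sd=sb),
        )
        ests[r], variances[r] = c.estimate, c.variance
    mc_se = ests.std(ddof=1) / math.sqrt(reps)
    assert abs(ests.mean() - truth) < 3 * mc_se
    assert abs(variances.mean() - ests.var(ddof=1)) / ests.var(ddof=1) < 0.10
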