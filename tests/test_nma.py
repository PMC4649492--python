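"""The Bayesian NMA engine: model structure, sampler correctness against
conjugate closed forms, posterior summaries, residual deviance and
convergence diagnostics."""

import math

import numpy as np
import pytest

from knee_nma.data import DisconnectedNetworkError, NetworkDataset, Trial
from knee_nma.effects import trial_contrasts
from knee_nma.nma import (
    McmcConfig,
    NmaModelSpec,
    PosteriorDraws,
    build_model,
    convergence_check,
    exchangeable_corr,
    residual_deviance,
    run_mcmc,
    summarize_posterior,
)

from conftest import binary_arm, continuous_arm, two_arm_continuous_dataset


def _two_treatment_binary_ds():
    trials = tuple(
        Trial(t, (binary_arm(t, "placebo", events=e0), binary_arm(t, "celecoxib", events=e1)))
        for t, e0, e1 in [("A", 10, 14), ("B", 8, 11), ("C", 12, 12)]
    )
    return NetworkDataset(trials=trials, outcome_kind="withdrawal_ae")


class TestBuildModel:
    def test_binary_two_treatment_structure(self):
        spec = build_model(_two_treatment_binary_ds())
        assert spec.likelihood == "binomial_logit"
        assert spec.n_basic_parameters == 1
        assert len(spec.trials) == 3  # one mu per trial
        assert spec.n_data_points == 6  # arms

    def test_five_treatment_basic_parameters(self, pain_network):
        ds, _ = pain_network
        spec = build_model(ds)
        assert spec.n_basic_parameters == 4
        # all 10 unordered pairwise contrasts are expressible by consistency
        assert len(spec.treatments) * (len(spec.treatments) - 1) // 2 == 10

    def test_disconnected_network_refused(self):
        ds = two_arm_continuous_dataset(
            [
                ("T1", "placebo", -1.0, "glucosamine", -1.2),
                ("T2", "chondroitin", -1.0, "celecoxib", -1.2),
            ]
        )
        with pytest.raises(DisconnectedNetworkError, match="components"):
            build_model(ds)

    def test_multiarm_conditional_variance(self):
        """The exchangeable covariance (tau^2 diag, tau^2/2 off-diagonal)
        implies the sequential construction's conditional variance
        tau^2 * k / (2(k-1)) for arm k."""
        tau2 = 0.7
        for m, k in [(2, 3), (3, 4)]:
            cov = tau2 * exchangeable_corr(m)
            s11 = cov[:-1, :-1]
            s12 = cov[:-1, -1]
            cond_var = cov[-1, -1] - s12 @ np.linalg.solve(s11, s12)
            assert cond_var == pytest.approx(tau2 * k / (2 * (k - 1)))


class TestSampler:
    def test_conjugate_fixed_effect_oracle(self):
        """With tau fixed at zero and an effectively flat prior the posterior
        of the basic parameter is the closed-form inverse-variance normal."""
        ds = two_arm_continuous_dataset(
            [
                ("A", "placebo", -1.0, "glucosamine", -1.6),
                ("B", "placebo", -0.9, "glucosamine", -1.4),
                ("C", "placebo", -1.2, "glucosamine", -1.5),
            ]
        )
        spec = build_model(ds, tau_fixed=0.0)
        draws = run_mcmc(spec, McmcConfig(n_chains=2, n_iter=6000, n_burn=1000, base_seed=4))
        x = draws.pooled_d()[:, 1]
        y = np.array([trial_contrasts(t, "smd").contrasts[0].estimate for t in ds.trials])
        v = np.array([trial_contrasts(t, "smd").contrasts[0].variance for t in ds.trials])
        prec = (1 / v).sum() + 1e-4
        mean, sd = (y / v).sum() / prec, math.sqrt(1 / prec)
        n = len(x)
        assert abs(x.mean() - mean) < 3 * sd / math.sqrt(n)
        assert abs(x.std(ddof=1) - sd) < 3 * sd / math.sqrt(2 * n)

    def test_identical_arms_posterior_centred_at_zero(self):
        ds = two_arm_continuous_dataset(
            [(f"T{i}", "placebo", -1.0, "glucosamine", -1.0) for i in range(4)]
        )
        draws = run_mcmc(build_model(ds), McmcConfig(n_chains=2, n_iter=4000, n_burn=1000, base_seed=8))
        med = np.median(draws.pooled_d()[:, 1])
        assert abs(med) < 0.05

    def test_single_trial_vague_prior_tracks_likelihood(self):
        """One two-arm trial with v ~ 0.01: the posterior median of the
        contrast is within 0.02 of the observed contrast."""
        ds = two_arm_continuous_dataset([("A", "placebo", -1.0, "glucosamine", -2.0)], "pain_smd")
        # shrink the contrast variance by inflating n
        from knee_nma.data import NetworkDataset, Trial
        from conftest import continuous_arm

        big = NetworkDataset(
            trials=(
                Trial(
                    "A",
                    (
                        continuous_arm("A", "placebo", n=220, mean=-1.0),
                        continuous_arm("A", "glucosamine", n=220, mean=-2.0),
                    ),
                ),
            ),
            outcome_kind="pain_smd",
        )
        spec = build_model(big)
        obs = trial_contrasts(big.trials[0], "smd").contrasts[0]
        assert obs.variance < 0.011
        draws = run_mcmc(spec, McmcConfig(n_chains=3, n_iter=8000, n_burn=2000, base_seed=6))
        assert abs(np.median(draws.pooled_d()[:, 1]) - obs.estimate) < 0.02

    def test_prior_predictive_sd(self):
        """With no data, basic-parameter draws have SD ~ 100 = sqrt(10^4)."""
        spec = NmaModelSpec(
            likelihood="normal_contrast",
            measure="smd",
            treatments=("placebo", "glucosamine"),
            reference="placebo",
            tau_upper=2.0,
            contrasts=(),
        )
        draws = run_mcmc(spec, McmcConfig(n_chains=2, n_iter=11000, n_burn=1000, base_seed=12))
        sd = draws.pooled_d()[:, 1].std()
        assert 95 < sd < 105

    def test_bitwise_reproducible(self, pain_network):
        ds, _ = pain_network
        spec = build_model(ds)
        cfg = McmcConfig(n_chains=2, n_iter=600, n_burn=200, base_seed=3)
        d1 = run_mcmc(spec, cfg)
        d2 = run_mcmc(spec, cfg)
        assert np.array_equal(d1.d, d2.d)
        assert np.array_equal(d1.tau, d2.tau)
        frame = d1.to_frame()
        assert list(frame.columns[:2]) == ["chain", "iteration"]
        assert len(frame) == d1.n_draws
        assert frame.iteration.min() == 200

    def test_rhat_agrees_with_arviz(self, pain_network):
        import arviz as az

        ds, _ = pain_network
        draws = run_mcmc(build_model(ds), McmcConfig(n_chains=3, n_iter=1500, n_burn=500, base_seed=2))
        ours = convergence_check(draws)
        ref = az.rhat(az.convert_to_dataset(draws.d[:, :, 4]))
        assert ours.set_index("parameter").loc["d[celecoxib]", "rhat"] == pytest.approx(
            float(ref.x), abs=0.01
        )

    def test_reference_relabelling_leaves_contrasts_invariant(self):
        ds = two_arm_continuous_dataset(
            [
                ("A", "placebo", -1.0, "glucosamine", -1.6),
                ("B", "placebo", -0.9, "glucosamine", -1.2),
                ("C", "glucosamine", -1.2, "celecoxib", -1.6),
                ("D", "placebo", -1.0, "celecoxib", -1.7),
                ("E", "placebo", -1.1, "celecoxib", -1.6),
            ]
        )
        cfg = McmcConfig(n_chains=2, n_iter=6000, n_burn=2000, base_seed=10)
        d_ref_pl = run_mcmc(build_model(ds, reference="placebo"), cfg)
        d_ref_glu = run_mcmc(build_model(ds, reference="glucosamine"), cfg)
        for a, b in [("placebo", "celecoxib"), ("glucosamine", "celecoxib")]:
            m1 = np.median(d_ref_pl.contrast_draws(a, b))
            m2 = np.median(d_ref_glu.contrast_draws(a, b))
            assert abs(m1 - m2) < 0.05


def _degenerate_draws(values, treatments=("placebo", "glucosamine"), measure="smd"):
    arr = np.asarray(values, dtype=float)
    C, T, K = arr.shape
    return PosteriorDraws(
        treatments=tuple(treatments),
        reference=treatments[0],
        measure=measure,
        likelihood="normal_contrast",
        d=arr,
        tau=np.zeros((C, T)),
        delta=np.zeros((C, T, 0)),
        mu=None,
        contrast_labels=(),
        seeds=tuple(range(C)),
        n_iter=T,
        n_burn=0,
        thinning=1,
    )


class TestSummaries:
    def test_degenerate_draws_collapse_interval(self):
        d = np.zeros((1, 100, 2))
        d[:, :, 1] = 0.7
        lt = summarize_posterior(_degenerate_draws(d))
        e = lt.entry("placebo", "glucosamine")
        assert (e["median"], e.ci_low, e.ci_high) == (0.7, 0.7, 0.7)
        assert e.significant

    def test_league_antisymmetry_per_draw(self):
        rng = np.random.default_rng(0)
        d = np.zeros((2, 500, 3))
        d[:, :, 1:] = rng.normal(size=(2, 500, 2))
        lt = summarize_posterior(
            _degenerate_draws(d, treatments=("placebo", "glucosamine", "celecoxib"))
        )
        for a, b in [("placebo", "glucosamine"), ("glucosamine", "celecoxib")]:
            fwd, rev = lt.entry(a, b), lt.entry(b, a)
            assert fwd["median"] == pytest.approx(-rev["median"], abs=1e-12)
            assert fwd.ci_low == pytest.approx(-rev.ci_high, abs=1e-12)

    def test_percentiles_match_analytic_normal(self):
        rng = np.random.default_rng(99)
        d = np.zeros((1, 40_000, 2))
        d[0, :, 1] = rng.standard_normal(40_000)
        e = summarize_posterior(_degenerate_draws(d)).entry("placebo", "glucosamine")
        assert e.ci_low == pytest.approx(-1.96, abs=0.05)
        assert e.ci_high == pytest.approx(1.96, abs=0.05)


class TestResidualDeviance:
    def test_zero_when_fitted_equals_observed(self):
        ds = two_arm_continuous_dataset(
            [("A", "placebo", -1.0, "glucosamine", -1.6), ("B", "placebo", -1.0, "glucosamine", -1.3)]
        )
        spec = build_model(ds)
        obs = np.array(
            [trial_contrasts(t, "smd").contrasts[0].estimate for t in ds.trials]
        )
        draws = PosteriorDraws(
            treatments=spec.treatments,
            reference="placebo",
            measure="smd",
            likelihood="normal_contrast",
            d=np.zeros((1, 10, 2)),
            tau=np.zeros((1, 10)),
            delta=np.tile(obs, (1, 10, 1)),
            mu=None,
            contrast_labels=spec.contrast_labels,
            seeds=(0,),
            n_iter=10,
            n_burn=0,
            thinning=1,
        )
        fit = residual_deviance(draws, spec)
        assert fit.total == pytest.approx(0.0, abs=1e-12)
        assert fit.n_points == 2

    def test_corrupted_arm_dominates_per_point_deviance(self):
        """Inflating one arm's event count five-fold makes that arm the
        worst-fitting data point."""
        trials = []
        for i in range(8):
            tid = f"T{i}"
            trials.append(
                Trial(
                    tid,
                    (binary_arm(tid, "placebo", n=200, events=28 + i % 3),
                     binary_arm(tid, "celecoxib", n=200, events=30 - i % 3)),
                )
            )
        # corrupt the last trial's celecoxib arm
        tid = "T9"
        trials.append(
            Trial(tid, (binary_arm(tid, "placebo", n=200, events=30),
                        binary_arm(tid, "celecoxib", n=200, events=150)))
        )
        ds = NetworkDataset(trials=tuple(trials), outcome_kind="withdrawal_ae")
        spec = build_model(ds)
        draws = run_mcmc(spec, McmcConfig(n_chains=2, n_iter=3000, n_burn=1000, base_seed=21))
        fit = residual_deviance(draws, spec)
        worst = fit.per_point.loc[fit.per_point.mean_deviance.idxmax()]
        assert worst.trial_id == "T9" and worst.treatment == "celecoxib"


class TestConvergence:
    def test_null_case_near_one_and_separation_flagged(self):
        rng = np.random.default_rng(3)
        same = _degenerate_draws(
            np.concatenate(
                [np.zeros((3, 2000, 1)), rng.standard_normal((3, 2000, 1))], axis=2
            )
        )
        df = convergence_check(same)
        assert abs(df.rhat.iloc[0] - 1.0) < 0.02

        apart = rng.standard_normal((3, 2000, 2))
        apart[:, :, 1] += np.array([0.0, 5.0, 10.0])[:, None]
        df2 = convergence_check(_degenerate_draws(apart))
        assert df2.rhat.iloc[0] > 1.05 and df2.flagged.iloc[0]

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            convergence_check(_degenerate_draws(np.zeros((1, 100, 2))))

    def test_fitted_network_converges(self, pain_network):
        ds, _ = pain_network
        draws = run_mcmc(
            build_model(ds), McmcConfig(n_chains=3, n_iter=4000, n_burn=1000, base_seed=15)
        )
        df = convergence_check(draws)
        assert (df.rhat < 1.05).all()
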