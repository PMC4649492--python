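"""Bayesian random-effects network meta-analysis fitted by Metropolis-within-Gibbs.

Model
-----
Basic parameters d_k are relative effects of each treatment versus the
reference (placebo); consistency defines every other contrast as
d_bk = d_k - d_b. Trial-specific effects delta_i deviate from the
consistency means with a single shared between-trial SD tau ("homogeneous
variance"): for a trial with m contrasts against its baseline arm the
random-effects covariance is exchangeable, tau^2 on the diagonal and
tau^2/2 off-diagonal — the joint form of the usual sequential conditional
construction for multi-arm trials (arm j given earlier arms has conditional
variance tau^2 * j / (2(j-1))).

Likelihoods:

* ``normal_contrast`` (SMD / MD): the observed per-trial contrast vector is
  multivariate normal around delta_i with the known sampling covariance S_i;
* ``binomial_logit`` (adverse events): arm-level events are
  Binomial(n_ik, p_ik) with logit(p_ik) = mu_i + delta_ik and delta of the
  baseline arm identically zero.

Priors: d_k and mu_i ~ Normal(0, 10^4); tau ~ Uniform(0, 2) on the SMD/MD
scale or Uniform(0, 5) on the log-odds scale.

Sampling
--------
Conjugate normal nodes (delta and d in the contrast model, d given deltas in
the binomial model) are updated by Gibbs; mu, non-conjugate deltas and tau
use adaptive random-walk Metropolis with step-size adaptation frozen at the
end of burn-in so the post-burn-in kernel satisfies detailed balance. Runs
are bitwise reproducible given the chain seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, xlogy

from .data import (
    BINARY_KINDS,
    CONTINUOUS_KINDS,
    DisconnectedNetworkError,
    NetworkDataset,
    Trial,
    check_connectivity,
)
from .effects import TrialContrasts, trial_contrasts

PRIOR_VARIANCE = 1.0e4  # vague normal prior for location parameters
TAU_UPPER = {"smd": 2.0, "md": 2.0, "log_or": 5.0}

_MEASURE_FOR_KIND = {
    **{k: "smd" for k in CONTINUOUS_KINDS},
    "jsw_md": "md",
    **{k: "log_or" for k in BINARY_KINDS},
}


def measure_for_outcome(outcome_kind: str) -> str:
    return _MEASURE_FOR_KIND[outcome_kind]


def exchangeable_corr(m: int) -> np.ndarray:
    """Correlation-like matrix R of the multi-arm random-effects covariance
    tau^2 * R: ones on the diagonal, 1/2 off-diagonal."""
    return 0.5 * (np.eye(m) + np.ones((m, m)))


@dataclass(frozen=True)
class McmcConfig:
    """Chain layout. Defaults: 3 chains of 50,000 iterations, first 10,000
    discarded as burn-in, no thinning."""

    n_chains: int = 3
    n_iter: int = 50_000
    n_burn: int = 10_000
    seeds: tuple[int, ...] | None = None
    thinning: int = 1
    base_seed: int = 2015

    def __post_init__(self) -> None:
        if not 0 <= self.n_burn < self.n_iter:
            raise ValueError("need 0 <= n_burn < n_iter")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.seeds is not None:
            if len(self.seeds) != self.n_chains:
                raise ValueError("one seed per chain required")
            if len(set(self.seeds)) != self.n_chains:
                raise ValueError("chain seeds must be distinct")

    def chain_seeds(self) -> tuple[int, ...]:
        if self.seeds is not None:
            return tuple(self.seeds)
        ss = np.random.SeedSequence(self.base_seed)
        return tuple(int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(self.n_chains))

    @property
    def n_keep(self) -> int:
        return (self.n_iter - self.n_burn) // self.thinning


@dataclass(frozen=True)
class NmaModelSpec:
    likelihood: str  # "normal_contrast" | "binomial_logit"
    measure: str  # "smd" | "md" | "log_or"
    treatments: tuple[str, ...]
    reference: str
    tau_upper: float
    prior_variance: float = PRIOR_VARIANCE
    tau_fixed: float | None = None
    contrasts: tuple[TrialContrasts, ...] | None = None  # normal likelihood
    trials: tuple[Trial, ...] | None = None  # binomial likelihood

    @property
    def n_treatments(self) -> int:
        return len(self.treatments)

    @property
    def n_basic_parameters(self) -> int:
        return self.n_treatments - 1

    @property
    def n_data_points(self) -> int:
        """Arms for the binomial model, contrasts for the normal model."""
        if self.likelihood == "binomial_logit":
            return sum(len(t.arms) for t in self.trials)
        return sum(len(tc.contrasts) for tc in self.contrasts)

    @property
    def contrast_labels(self) -> tuple[tuple[str, str, str], ...]:
        """(trial_id, baseline, treatment) per stored delta, in data order."""
        labels = []
        if self.likelihood == "normal_contrast":
            for tc in self.contrasts:
                for c in tc.contrasts:
                    labels.append((tc.trial_id, c.treat_a, c.treat_b))
        else:
            for t in self.trials:
                for arm in t.arms[1:]:
                    labels.append((t.trial_id, t.baseline, arm.treatment))
        return tuple(labels)


def build_model(
    ds: NetworkDataset,
    measure: str | None = None,
    reference: str = "placebo",
    tau_fixed: float | None = None,
) -> NmaModelSpec:
    """Assemble the NMA model for a connected dataset.

    Binary outcome kinds map to the arm-based binomial-logit model; continuous
    and joint-space-width kinds to the contrast-based normal model.
    """
    report = check_connectivity(ds)
    if not report.connected:
        raise DisconnectedNetworkError([set(c) for c in report.components])
    if measure is None:
        measure = measure_for_outcome(ds.outcome_kind)
    treatments = ds.treatments
    if reference not in treatments:
        raise ValueError(f"reference {reference!r} not in network")
    likelihood = "binomial_logit" if measure == "log_or" else "normal_contrast"
    kwargs: dict = {}
    if likelihood == "normal_contrast":
        kwargs["contrasts"] = tuple(trial_contrasts(t, measure) for t in ds.trials)
    else:
        kwargs["trials"] = tuple(ds.trials)
    return NmaModelSpec(
        likelihood=likelihood,
        measure=measure,
        treatments=treatments,
        reference=reference,
        tau_upper=TAU_UPPER[measure],
        tau_fixed=tau_fixed,
        **kwargs,
    )


@dataclass
class PosteriorDraws:
    """Retained MCMC output with chain structure.

    ``d`` holds the basic parameters on the treatment axis in the model's
    canonical treatment order; the reference column is identically zero.
    """

    treatments: tuple[str, ...]
    reference: str
    measure: str
    likelihood: str
    d: np.ndarray  # (chains, draws, K)
    tau: np.ndarray  # (chains, draws)
    delta: np.ndarray  # (chains, draws, n_contrasts)
    mu: np.ndarray | None  # (chains, draws, n_trials) binomial only
    contrast_labels: tuple
    seeds: tuple[int, ...]
    n_iter: int
    n_burn: int
    thinning: int

    @property
    def n_chains(self) -> int:
        return self.d.shape[0]

    @property
    def n_draws(self) -> int:
        """Total retained draws pooled over chains."""
        return self.d.shape[0] * self.d.shape[1]

    def pooled_d(self) -> np.ndarray:
        return self.d.reshape(-1, self.d.shape[2])

    def pooled_tau(self) -> np.ndarray:
        return self.tau.reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        """Columnar export: one row per retained draw with chain and
        iteration columns, one column per basic parameter, plus tau."""
        C, T, K = self.d.shape
        chains = np.repeat(np.arange(C), T)
        iterations = np.tile(self.n_burn + self.thinning * np.arange(T), C)
        data = {"chain": chains, "iteration": iterations}
        ref = self.treatments.index(self.reference)
        dd = self.pooled_d()
        for k, name in enumerate(self.treatments):
            if k == ref:
                continue
            data[f"d[{name}]"] = dd[:, k]
        data["tau"] = self.pooled_tau()
        return pd.DataFrame(data)

    def contrast_draws(self, treat_a: str, treat_b: str) -> np.ndarray:
        """Per-draw consistency contrast of ``treat_b`` versus ``treat_a``."""
        ia = self.treatments.index(treat_a)
        ib = self.treatments.index(treat_b)
        dd = self.pooled_d()
        return dd[:, ib] - dd[:, ia]


# --------------------------------------------------------------------------
# sampler internals


class _NormalData:
    """Precomputed arrays for the contrast-likelihood sampler."""

    def __init__(self, spec: NmaModelSpec):
        K = spec.n_treatments
        tindex = {t: i for i, t in enumerate(spec.treatments)}
        ref = tindex[spec.reference]
        self.K, self.ref = K, ref
        self.free = np.array([i for i in range(K) if i != ref], dtype=int)

        two_y, two_v, two_t, two_b, two_pos = [], [], [], [], []
        multi = []
        pos = 0
        for tc in spec.contrasts:
            m = len(tc.contrasts)
            if m == 1:
                c = tc.contrasts[0]
                two_y.append(c.estimate)
                two_v.append(c.variance)
                two_t.append(tindex[c.treat_b])
                two_b.append(tindex[c.treat_a])
                two_pos.append(pos)
            else:
                y = tc.estimates
                S = tc.covariance
                R = exchangeable_corr(m)
                multi.append(
                    {
                        "y": y,
                        "Sinv": np.linalg.inv(S),
                        "Rinv": np.linalg.inv(R),
                        "t": np.array([tindex[c.treat_b] for c in tc.contrasts]),
                        "b": tindex[tc.contrasts[0].treat_a],
                        "pos": np.arange(pos, pos + m),
                    }
                )
            pos += m
        self.n_contrasts = pos
        self.y2 = np.array(two_y)
        self.v2 = np.array(two_v)
        self.t2 = np.array(two_t, dtype=int)
        self.b2 = np.array(two_b, dtype=int)
        self.pos2 = np.array(two_pos, dtype=int)
        self.multi = multi

        # sum of X' R^-1 X over trials, restricted to free parameters
        M = np.zeros((K, K))
        np.add.at(M, (self.t2, self.t2), 1.0)
        np.add.at(M, (self.b2, self.b2), 1.0)
        np.add.at(M, (self.t2, self.b2), -1.0)
        np.add.at(M, (self.b2, self.t2), -1.0)
        for tr in multi:
            X = np.zeros((len(tr["t"]), K))
            X[np.arange(len(tr["t"])), tr["t"]] = 1.0
            X[:, tr["b"]] -= 1.0
            M += X.T @ tr["Rinv"] @ X
            tr["X"] = X
        self.M_free = M[np.ix_(self.free, self.free)]

        # fixed-effect (tau = 0) exact posterior pieces: sum X' S^-1 X, X' S^-1 y
        A = np.zeros((K, K))
        bvec = np.zeros(K)
        w2 = 1.0 / self.v2 if len(self.v2) else self.v2
        np.add.at(A, (self.t2, self.t2), w2)
        np.add.at(A, (self.b2, self.b2), w2)
        np.add.at(A, (self.t2, self.b2), -w2)
        np.add.at(A, (self.b2, self.t2), -w2)
        np.add.at(bvec, self.t2, w2 * self.y2)
        np.add.at(bvec, self.b2, -w2 * self.y2)
        for tr in multi:
            A += tr["X"].T @ tr["Sinv"] @ tr["X"]
            bvec += tr["X"].T @ (tr["Sinv"] @ tr["y"])
        self.A0_free = A[np.ix_(self.free, self.free)]
        self.b0_free = bvec[self.free]


def _chain_inits(spec: NmaModelSpec, chain: int) -> tuple[float, float]:
    """Dispersed but deterministic initial values: d offset and tau quantile."""
    offset = ((chain % 3) - 1) * 0.5
    tau0 = (0.1, 0.5, 0.9)[chain % 3] * spec.tau_upper
    if spec.tau_fixed is not None:
        tau0 = spec.tau_fixed
    return offset, tau0


def _run_chain_normal(
    spec: NmaModelSpec, prep: _NormalData, cfg: McmcConfig, seed: int, chain: int
):
    rng = np.random.default_rng(seed)
    K, free = prep.K, prep.free
    Kf = len(free)
    offset, tau = _chain_inits(spec, chain)
    d = np.zeros(K)
    d[free] = offset
    prior_prec = 1.0 / spec.prior_variance
    n2 = len(prep.y2)
    delta2 = prep.y2.copy()
    delta_m = [tr["y"].copy() for tr in prep.multi]

    n_keep = cfg.n_keep
    out_d = np.empty((n_keep, K))
    out_tau = np.empty(n_keep)
    out_delta = np.empty((n_keep, prep.n_contrasts))

    fixed0 = spec.tau_fixed is not None and spec.tau_fixed == 0.0
    sample_tau = spec.tau_fixed is None
    m_total = float(prep.n_contrasts)
    step_tau = 0.1 * spec.tau_upper
    eyef = np.eye(Kf)

    if fixed0:
        A = prep.A0_free + prior_prec * eyef
        L = np.linalg.cholesky(A)
        mean0 = np.linalg.solve(A, prep.b0_free)
        Linv_t = np.linalg.inv(L).T

    kept = 0
    for it in range(cfg.n_iter):
        if fixed0:
            d[free] = mean0 + Linv_t @ rng.standard_normal(Kf)
            if n2:
                delta2 = d[prep.t2] - d[prep.b2]
            delta_m = [d[tr["t"]] - d[tr["b"]] for tr in prep.multi]
        else:
            tau2 = tau * tau
            # delta | y, d, tau  (conjugate normal)
            if n2:
                m2 = d[prep.t2] - d[prep.b2]
                prec = 1.0 / prep.v2 + 1.0 / tau2
                mean = (prep.y2 / prep.v2 + m2 / tau2) / prec
                delta2 = mean + rng.standard_normal(n2) / np.sqrt(prec)
            for j, tr in enumerate(prep.multi):
                mu_m = d[tr["t"]] - d[tr["b"]]
                P = tr["Sinv"] + tr["Rinv"] / tau2
                Lp = np.linalg.cholesky(P)
                rhs = tr["Sinv"] @ tr["y"] + (tr["Rinv"] @ mu_m) / tau2
                mean_m = np.linalg.solve(P, rhs)
                z = rng.standard_normal(len(mu_m))
                delta_m[j] = mean_m + np.linalg.solve(Lp.T, z)
            # d | delta, tau  (conjugate normal)
            bfull = np.zeros(K)
            if n2:
                np.add.at(bfull, prep.t2, delta2)
                np.add.at(bfull, prep.b2, -delta2)
            for j, tr in enumerate(prep.multi):
                u = tr["Rinv"] @ delta_m[j]
                np.add.at(bfull, tr["t"], u)
                bfull[tr["b"]] -= u.sum()
            A = prep.M_free / tau2 + prior_prec * eyef
            La = np.linalg.cholesky(A)
            mean_d = np.linalg.solve(A, bfull[free] / tau2)
            d[free] = mean_d + np.linalg.solve(La.T, rng.standard_normal(Kf))
            # tau | delta, d  (random-walk Metropolis, uniform prior)
            if sample_tau:
                Qsum = 0.0
                if n2:
                    r2 = delta2 - (d[prep.t2] - d[prep.b2])
                    Qsum += float((r2 * r2 / 1.0).sum())
                for j, tr in enumerate(prep.multi):
                    r = delta_m[j] - (d[tr["t"]] - d[tr["b"]])
                    Qsum += float(r @ tr["Rinv"] @ r)

                def logpost(t: float) -> float:
                    return -m_total * math.log(t) - Qsum / (2.0 * t * t)

                prop = tau + step_tau * rng.standard_normal()
                accepted = 0.0
                if 0.0 < prop < spec.tau_upper:
                    if m_total == 0 or math.log(rng.uniform()) < logpost(prop) - logpost(tau):
                        tau = prop
                        accepted = 1.0
                if it < cfg.n_burn:
                    step_tau *= math.exp((accepted - 0.44) / (1.0 + it) ** 0.6)

        if it >= cfg.n_burn and (it - cfg.n_burn) % cfg.thinning == 0:
            out_d[kept] = d
            out_tau[kept] = tau if not fixed0 else 0.0
            if n2:
                out_delta[kept, prep.pos2] = delta2
            for j, tr in enumerate(prep.multi):
                out_delta[kept, tr["pos"]] = delta_m[j]
            kept += 1
    return out_d[:kept], out_tau[:kept], out_delta[:kept]


class _BinomData:
    """Precomputed arrays for the arm-based binomial-logit sampler."""

    def __init__(self, spec: NmaModelSpec):
        K = len(spec.treatments)
        tindex = {t: i for i, t in enumerate(spec.treatments)}
        ref = tindex[spec.reference]
        self.K, self.ref = K, ref
        self.free = np.array([i for i in range(K) if i != ref], dtype=int)

        arm_trial, arm_treat, arm_n, arm_e, arm_dcol = [], [], [], [], []
        two = {"dcol": [], "trial": [], "arm": [], "t": [], "b": []}
        multi = []
        mu0 = []
        dcol = 0
        for ti, trial in enumerate(spec.trials):
            base = trial.arms[0]
            mu0.append(math.log((base.events + 0.5) / (base.n - base.events + 0.5)))
            cols = []
            arm_ids = []
            for ai, arm in enumerate(trial.arms):
                arm_trial.append(ti)
                arm_treat.append(tindex[arm.treatment])
                arm_n.append(arm.n)
                arm_e.append(arm.events)
                if ai == 0:
                    arm_dcol.append(-1)
                else:
                    arm_dcol.append(dcol)
                    cols.append(dcol)
                    arm_ids.append(len(arm_trial) - 1)
                    dcol += 1
            m = len(trial.arms) - 1
            if m == 1:
                two["dcol"].append(cols[0])
                two["trial"].append(ti)
                two["arm"].append(arm_ids[0])
                two["t"].append(tindex[trial.arms[1].treatment])
                two["b"].append(tindex[base.treatment])
            else:
                multi.append(
                    {
                        "cols": np.array(cols),
                        "arms": np.array(arm_ids),
                        "t": np.array([tindex[a.treatment] for a in trial.arms[1:]]),
                        "b": tindex[base.treatment],
                        "trial": ti,
                        "Rinv": np.linalg.inv(exchangeable_corr(m)),
                    }
                )
        self.n_trials = len(spec.trials)
        self.n_delta = dcol
        self.arm_trial = np.array(arm_trial, dtype=int)
        self.arm_treat = np.array(arm_treat, dtype=int)
        self.arm_n = np.array(arm_n, dtype=float)
        self.arm_e = np.array(arm_e, dtype=float)
        self.arm_dcol = np.array(arm_dcol, dtype=int)
        self.two = {k: np.array(v, dtype=int) for k, v in two.items()}
        self.multi = multi
        self.mu0 = np.array(mu0)

        M = np.zeros((K, K))
        t2, b2 = self.two["t"], self.two["b"]
        np.add.at(M, (t2, t2), 1.0)
        np.add.at(M, (b2, b2), 1.0)
        np.add.at(M, (t2, b2), -1.0)
        np.add.at(M, (b2, t2), -1.0)
        for tr in multi:
            X = np.zeros((len(tr["t"]), K))
            X[np.arange(len(tr["t"])), tr["t"]] = 1.0
            X[:, tr["b"]] -= 1.0
            M += X.T @ tr["Rinv"] @ X
            tr["X"] = X
        self.M_free = M[np.ix_(self.free, self.free)]

    def arm_loglik(self, theta: np.ndarray) -> np.ndarray:
        """Binomial log-likelihood per arm (up to the constant term)."""
        return self.arm_e * theta - self.arm_n * np.logaddexp(0.0, theta)


def _run_chain_binom(
    spec: NmaModelSpec, prep: _BinomData, cfg: McmcConfig, seed: int, chain: int
):
    rng = np.random.default_rng(seed)
    K, free = prep.K, prep.free
    Kf = len(free)
    offset, tau = _chain_inits(spec, chain)
    d = np.zeros(K)
    d[free] = offset
    prior_prec = 1.0 / spec.prior_variance
    mu = prep.mu0.copy()
    delta = np.zeros(prep.n_delta)
    # initialize deltas at the consistency means implied by the initial d
    delta_arm = np.zeros(len(prep.arm_trial))
    nb = prep.arm_dcol >= 0

    t2, b2 = prep.two["t"], prep.two["b"]
    c2, tr2, a2 = prep.two["dcol"], prep.two["trial"], prep.two["arm"]
    delta[c2] = d[t2] - d[b2]
    for tr in prep.multi:
        delta[tr["cols"]] = d[tr["t"]] - d[tr["b"]]

    n_keep = cfg.n_keep
    out_d = np.empty((n_keep, K))
    out_tau = np.empty(n_keep)
    out_delta = np.empty((n_keep, prep.n_delta))
    out_mu = np.empty((n_keep, prep.n_trials))

    sample_tau = spec.tau_fixed is None
    fixed0 = spec.tau_fixed is not None and spec.tau_fixed == 0.0
    m_total = float(prep.n_delta)
    step_mu = np.full(prep.n_trials, 0.5)
    step_d1 = np.full(len(c2), 0.5)
    step_dm = [0.3] * len(prep.multi)
    step_df = np.full(Kf, 0.2)  # componentwise d steps, tau_fixed == 0 only
    step_tau = 0.1 * spec.tau_upper
    eyef = np.eye(Kf)

    e2 = prep.arm_e[a2]
    nn2 = prep.arm_n[a2]

    kept = 0
    for it in range(cfg.n_iter):
        adapting = it < cfg.n_burn
        gamma = (1.0 + it) ** -0.6
        if fixed0:
            delta[c2] = d[t2] - d[b2]
            for tr in prep.multi:
                delta[tr["cols"]] = d[tr["t"]] - d[tr["b"]]
        # --- mu: joint vectorized random-walk Metropolis over trials
        delta_arm[:] = 0.0
        delta_arm[nb] = delta[prep.arm_dcol[nb]]
        theta = mu[prep.arm_trial] + delta_arm
        ll_cur = np.bincount(prep.arm_trial, prep.arm_loglik(theta), minlength=prep.n_trials)
        mu_prop = mu + step_mu * rng.standard_normal(prep.n_trials)
        theta_p = mu_prop[prep.arm_trial] + delta_arm
        ll_prop = np.bincount(prep.arm_trial, prep.arm_loglik(theta_p), minlength=prep.n_trials)
        logr = ll_prop - ll_cur + (mu * mu - mu_prop * mu_prop) * (0.5 * prior_prec)
        acc = np.log(rng.uniform(size=prep.n_trials)) < logr
        mu[acc] = mu_prop[acc]
        if adapting:
            step_mu *= np.exp(gamma * (acc.astype(float) - 0.44))

        if not fixed0:
            tau2 = tau * tau
            # --- two-arm deltas: vectorized random-walk Metropolis
            if len(c2):
                mcons = d[t2] - d[b2]
                cur = delta[c2]
                th = mu[tr2] + cur
                ll_c = e2 * th - nn2 * np.logaddexp(0.0, th)
                prop = cur + step_d1 * rng.standard_normal(len(c2))
                th_p = mu[tr2] + prop
                ll_p = e2 * th_p - nn2 * np.logaddexp(0.0, th_p)
                logr = ll_p - ll_c + ((cur - mcons) ** 2 - (prop - mcons) ** 2) / (2.0 * tau2)
                acc = np.log(rng.uniform(size=len(c2))) < logr
                delta[c2[acc]] = prop[acc]
                if adapting:
                    step_d1 *= np.exp(gamma * (acc.astype(float) - 0.44))
            # --- multi-arm deltas: joint random-walk per trial
            for j, tr in enumerate(prep.multi):
                cols = tr["cols"]
                cur = delta[cols]
                mcons = d[tr["t"]] - d[tr["b"]]
                e_m = prep.arm_e[tr["arms"]]
                n_m = prep.arm_n[tr["arms"]]
                th = mu[tr["trial"]] + cur
                ll_c = float((e_m * th - n_m * np.logaddexp(0.0, th)).sum())
                rc = cur - mcons
                prior_c = -0.5 * float(rc @ tr["Rinv"] @ rc) / tau2
                prop = cur + step_dm[j] * rng.standard_normal(len(cols))
                th_p = mu[tr["trial"]] + prop
                ll_p = float((e_m * th_p - n_m * np.logaddexp(0.0, th_p)).sum())
                rp = prop - mcons
                prior_p = -0.5 * float(rp @ tr["Rinv"] @ rp) / tau2
                accepted = 0.0
                if math.log(rng.uniform()) < (ll_p + prior_p) - (ll_c + prior_c):
                    delta[cols] = prop
                    accepted = 1.0
                if adapting:
                    step_dm[j] *= math.exp(gamma * (accepted - 0.3))
            # --- d | delta, tau: conjugate normal
            bfull = np.zeros(K)
            np.add.at(bfull, t2, delta[c2])
            np.add.at(bfull, b2, -delta[c2])
            for tr in prep.multi:
                u = tr["Rinv"] @ delta[tr["cols"]]
                np.add.at(bfull, tr["t"], u)
                bfull[tr["b"]] -= u.sum()
            A = prep.M_free / tau2 + prior_prec * eyef
            La = np.linalg.cholesky(A)
            mean_d = np.linalg.solve(A, bfull[free] / tau2)
            d[free] = mean_d + np.linalg.solve(La.T, rng.standard_normal(Kf))
            # --- tau
            if sample_tau:
                Qsum = 0.0
                if len(c2):
                    r = delta[c2] - (d[t2] - d[b2])
                    Qsum += float((r * r).sum())
                for tr in prep.multi:
                    r = delta[tr["cols"]] - (d[tr["t"]] - d[tr["b"]])
                    Qsum += float(r @ tr["Rinv"] @ r)
                prop_t = tau + step_tau * rng.standard_normal()
                accepted = 0.0
                if 0.0 < prop_t < spec.tau_upper:
                    lp = -m_total * math.log(prop_t) - Qsum / (2.0 * prop_t * prop_t)
                    lc = -m_total * math.log(tau) - Qsum / (2.0 * tau2)
                    if m_total == 0 or math.log(rng.uniform()) < lp - lc:
                        tau = prop_t
                        accepted = 1.0
                if adapting:
                    step_tau *= math.exp(gamma * (accepted - 0.44))
        else:
            # tau fixed at zero: deltas are the consistency means; update the
            # basic parameters by componentwise random-walk Metropolis
            for jj, kidx in enumerate(free):
                cur = d[kidx]
                ll_c = float(prep.arm_loglik(mu[prep.arm_trial] + delta_arm_consistency(prep, d)).sum())
                d[kidx] = cur + step_df[jj] * rng.standard_normal()
                ll_p = float(prep.arm_loglik(mu[prep.arm_trial] + delta_arm_consistency(prep, d)).sum())
                logr = ll_p - ll_c + (cur * cur - d[kidx] * d[kidx]) * (0.5 * prior_prec)
                if math.log(rng.uniform()) < logr:
                    accepted = 1.0
                else:
                    d[kidx] = cur
                    accepted = 0.0
                if adapting:
                    step_df[jj] *= math.exp(gamma * (accepted - 0.44))
            delta[c2] = d[t2] - d[b2]
            for tr in prep.multi:
                delta[tr["cols"]] = d[tr["t"]] - d[tr["b"]]

        if it >= cfg.n_burn and (it - cfg.n_burn) % cfg.thinning == 0:
            out_d[kept] = d
            out_tau[kept] = tau if not fixed0 else 0.0
            out_delta[kept] = delta
            out_mu[kept] = mu
            kept += 1
    return out_d[:kept], out_tau[:kept], out_delta[:kept], out_mu[:kept]


def delta_arm_consistency(prep: _BinomData, d: np.ndarray) -> np.ndarray:
    """Per-arm delta implied by consistency (baseline arms zero)."""
    out = np.zeros(len(prep.arm_trial))
    nb = prep.arm_dcol >= 0
    # baseline treatment of each arm's trial
    base_treat = np.empty(prep.n_trials, dtype=int)
    first = np.full(prep.n_trials, -1, dtype=int)
    for i, ti in enumerate(prep.arm_trial):
        if first[ti] < 0:
            first[ti] = prep.arm_treat[i]
    out[nb] = d[prep.arm_treat[nb]] - d[first[prep.arm_trial[nb]]]
    return out


def run_mcmc(spec: NmaModelSpec, cfg: McmcConfig | None = None) -> PosteriorDraws:
    """Fit the model and return all retained draws with chain labels."""
    cfg = cfg or McmcConfig()
    seeds = cfg.chain_seeds()
    if spec.likelihood == "normal_contrast":
        prep = _NormalData(spec)
        results = [
            _run_chain_normal(spec, prep, cfg, seed, c) for c, seed in enumerate(seeds)
        ]
        d = np.stack([r[0] for r in results])
        tau = np.stack([r[1] for r in results])
        delta = np.stack([r[2] for r in results])
        mu = None
    else:
        prep = _BinomData(spec)
        results = [
            _run_chain_binom(spec, prep, cfg, seed, c) for c, seed in enumerate(seeds)
        ]
        d = np.stack([r[0] for r in results])
        tau = np.stack([r[1] for r in results])
        delta = np.stack([r[2] for r in results])
        mu = np.stack([r[3] for r in results])
    return PosteriorDraws(
        treatments=spec.treatments,
        reference=spec.reference,
        measure=spec.measure,
        likelihood=spec.likelihood,
        d=d,
        tau=tau,
        delta=delta,
        mu=mu,
        contrast_labels=spec.contrast_labels,
        seeds=seeds,
        n_iter=cfg.n_iter,
        n_burn=cfg.n_burn,
        thinning=cfg.thinning,
    )


# --------------------------------------------------------------------------
# posterior summaries


@dataclass(frozen=True)
class LeagueTable:
    """All pairwise posterior contrasts: median, 2.5th/97.5th percentiles and
    a significance flag (interval excluding 0, i.e. 1 on the OR scale)."""

    treatments: tuple[str, ...]
    measure: str
    table: pd.DataFrame  # columns: treat_a, treat_b, median, ci_low, ci_high, significant

    def entry(self, treat_a: str, treat_b: str) -> pd.Series:
        t = self.table
        row = t[(t.treat_a == treat_a) & (t.treat_b == treat_b)]
        if row.empty:
            raise KeyError((treat_a, treat_b))
        return row.iloc[0]

    def to_matrix(self) -> pd.DataFrame:
        """Square matrix of formatted 'median (low, high)' cells, column
        treatment versus row treatment."""
        k = len(self.treatments)
        mat = pd.DataFrame("-", index=self.treatments, columns=self.treatments)
        for _, row in self.table.iterrows():
            mat.loc[row.treat_a, row.treat_b] = (
                f"{row['median']:.2f} ({row.ci_low:.2f}, {row.ci_high:.2f})"
            )
        return mat


def summarize_posterior(draws: PosteriorDraws) -> LeagueTable:
    """League table from pooled post-burn-in chains.

    Percentiles are taken on the analysis scale; for the log-odds measure the
    exponentiated columns (``or_median`` etc.) are added after percentile
    extraction. Antisymmetry holds exactly per draw, hence exactly for the
    medians and (mirrored) interval bounds.
    """
    if draws.n_draws == 0:
        raise ValueError("no draws to summarize")
    dd = draws.pooled_d()
    rows = []
    ratio = draws.measure == "log_or"
    for i, ta in enumerate(draws.treatments):
        for j, tb in enumerate(draws.treatments):
            if i == j:
                continue
            x = dd[:, j] - dd[:, i]
            med = float(np.median(x))
            lo, hi = (float(q) for q in np.percentile(x, [2.5, 97.5]))
            row = {
                "treat_a": ta,
                "treat_b": tb,
                "median": med,
                "ci_low": lo,
                "ci_high": hi,
                "significant": bool(lo > 0.0 or hi < 0.0),
            }
            if ratio:
                row.update(
                    or_median=math.exp(med), or_ci_low=math.exp(lo), or_ci_high=math.exp(hi)
                )
            rows.append(row)
    return LeagueTable(treatments=draws.treatments, measure=draws.measure, table=pd.DataFrame(rows))


@dataclass(frozen=True)
class DevianceSummary:
    total: float
    n_points: int
    per_point: pd.DataFrame  # label columns + mean_deviance

    @property
    def ratio(self) -> float:
        return self.total / self.n_points


def residual_deviance(draws: PosteriorDraws, spec: NmaModelSpec) -> DevianceSummary:
    """Posterior mean residual deviance, total and per data point.

    Normal likelihood: the Mahalanobis form (y - delta)' S^-1 (y - delta) per
    trial, attributed to contrasts via the squared standardized residual.
    Binomial likelihood: the usual binomial deviance per arm with fitted
    events n * expit(mu + delta).
    """
    C, T = draws.d.shape[0], draws.d.shape[1]
    ndraw = C * T
    if spec.likelihood == "normal_contrast":
        prep = _NormalData(spec)
        per = np.zeros(prep.n_contrasts)
        delta = draws.delta.reshape(ndraw, -1)
        if len(prep.pos2):
            r = prep.y2[None, :] - delta[:, prep.pos2]
            per[prep.pos2] = (r * r / prep.v2[None, :]).mean(axis=0)
        for tr in prep.multi:
            r = tr["y"][None, :] - delta[:, tr["pos"]]
            # mean over draws of r' Sinv r, attributed per-contrast via r * (Sinv r)
            si_r = r @ tr["Sinv"]
            per[tr["pos"]] = (r * si_r).mean(axis=0)
        labels = pd.DataFrame(
            list(spec.contrast_labels), columns=["trial_id", "treat_a", "treat_b"]
        )
        labels["mean_deviance"] = per
        return DevianceSummary(total=float(per.sum()), n_points=spec.n_data_points, per_point=labels)

    prep = _BinomData(spec)
    delta = draws.delta.reshape(ndraw, -1)
    mu = draws.mu.reshape(ndraw, -1)
    n_arms = len(prep.arm_trial)
    per = np.zeros(n_arms)
    e, n = prep.arm_e, prep.arm_n
    chunk = max(1, int(2_000_000 / max(n_arms, 1)))
    nb = prep.arm_dcol >= 0
    done = 0
    for start in range(0, ndraw, chunk):
        sl = slice(start, min(start + chunk, ndraw))
        theta = mu[sl][:, prep.arm_trial]
        theta[:, nb] += delta[sl][:, prep.arm_dcol[nb]]
        ehat = n[None, :] * expit(theta)
        dev = 2.0 * (
            xlogy(e[None, :], e[None, :] / ehat)
            + xlogy((n - e)[None, :], (n - e)[None, :] / (n[None, :] - ehat))
        )
        per += dev.sum(axis=0)
        done += sl.stop - sl.start
    per /= done
    rows = []
    for trial in spec.trials:
        for arm in trial.arms:
            rows.append({"trial_id": trial.trial_id, "treatment": arm.treatment})
    labels = pd.DataFrame(rows)
    labels["mean_deviance"] = per
    return DevianceSummary(total=float(per.sum()), n_points=spec.n_data_points, per_point=labels)


def split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for draws shaped
    (chains, iterations)."""
    C, T = x.shape
    half = T // 2
    if half < 2:
        raise ValueError("need at least 4 draws per chain")
    seqs = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, n = seqs.shape
    means = seqs.mean(axis=1)
    W = float(seqs.var(axis=1, ddof=1).mean())
    B_over_n = float(means.var(ddof=1))
    if W == 0.0:
        return 1.0
    var_plus = (n - 1) / n * W + B_over_n
    return math.sqrt(var_plus / W)


def convergence_check(draws: PosteriorDraws, threshold: float = 1.05) -> pd.DataFrame:
    """Split-chain PSRF per basic parameter and tau; parameters exceeding the
    threshold are flagged."""
    if draws.n_chains < 2:
        raise ValueError("convergence check requires at least 2 chains")
    rows = []
    ref = draws.treatments.index(draws.reference)
    for k, name in enumerate(draws.treatments):
        if k == ref:
            continue
        rows.append({"parameter": f"d[{name}]", "rhat": split_rhat(draws.d[:, :, k])})
    if draws.tau.std() > 0:
        rows.append({"parameter": "tau", "rhat": split_rhat(draws.tau)})
    df = pd.DataFrame(rows)
    df["flagged"] = df["rhat"] > threshold
    return df
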