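"""Synthetic trial-network generator with known truth.

Emulates the evidence base of the five-treatment knee-OA network: a
placebo-hub structure of 54 randomized trials (roughly 16,400 patients)
with a handful of head-to-head and multi-arm trials closing evidence loops,
generated under the consistency model with between-trial heterogeneity.

Generative model, per trial:

1. draw the trial's contrast vector delta against its baseline arm from
   Normal(consistency means, tau^2 * R) with the exchangeable multi-arm
   covariance R (unit diagonal, 1/2 off-diagonal);
2. continuous outcomes: arm-level true mean change = baseline change +
   delta * SD on the 0-10 scale; observed mean ~ Normal(truth, SD^2/n),
   observed SD ~ SD * sqrt(chi2(n-1)/(n-1)); rescaled to the trial's
   instrument (scale_max 10 or 100);
3. binary outcomes: trial baseline log-odds ~ Normal(logit(risk), sd);
   events ~ Binomial(n, expit(baseline + delta));
4. joint-space width: true narrowing = baseline narrowing - delta (a
   positive delta preserves joint space), observed like the continuous case.

The truth (basic parameters, tau, per-trial deltas) is written alongside
the dataset as JSON so recovery can be checked end to end.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit, logit

from .data import TREATMENT_INDEX, TREATMENTS, NetworkDataset, Trial, TrialArm, outcome_family
from .nma import exchangeable_corr

#: (treatments, number of trials, patients per arm) — a 54-trial network with
#: a placebo hub, the head-to-head edges needed for the celecoxib/glucosamine/
#: chondroitin and celecoxib/glucosamine/combination loops, and multi-arm
#: trials up to the full five-arm design. Total enrolment 16,725.
DEFAULT_DESIGNS: tuple[tuple[tuple[str, ...], int, int], ...] = (
    (("placebo", "celecoxib"), 14, 200),
    (("placebo", "glucosamine"), 10, 140),
    (("placebo", "chondroitin"), 9, 140),
    (("placebo", "glucosamine+chondroitin"), 4, 120),
    (("glucosamine", "celecoxib"), 4, 130),
    (("glucosamine", "chondroitin"), 3, 110),
    (("chondroitin", "celecoxib"), 2, 110),
    (("glucosamine", "glucosamine+chondroitin"), 2, 100),
    (("glucosamine+chondroitin", "celecoxib"), 2, 100),
    (("placebo", "glucosamine", "chondroitin", "glucosamine+chondroitin"), 1, 120),
    (("placebo", "glucosamine", "celecoxib"), 2, 150),
    (TREATMENTS, 1, 105),
)

#: True basic parameters per outcome kind (versus placebo, analysis scale).
#: The efficacy magnitudes correspond to the back-transformed clinical
#: differences of the motivating evidence base: e.g. an SMD of -0.27 is
#: -0.68 cm on a 10-cm VAS at a pooled SD of 2.5 cm (celecoxib, combination),
#: -0.50 cm -> -0.20 (glucosamine), -0.45 cm -> -0.18 (chondroitin); the
#: joint-space-width MDs (mm) and adverse-event log-odds follow the same
#: reported contrasts.
DEFAULT_TRUTH: dict[str, dict] = {
    "pain_smd": {
        "d": {
            "glucosamine": -0.20,
            "chondroitin": -0.18,
            "glucosamine+chondroitin": -0.27,
            "celecoxib": -0.27,
        },
        "tau": 0.2,
    },
    "function_smd": {
        "d": {
            "glucosamine": -0.19,
            "chondroitin": -0.13,
            "glucosamine+chondroitin": -0.23,
            "celecoxib": -0.28,
        },
        "tau": 0.15,
    },
    "jsw_md": {
        "d": {
            "glucosamine": 0.18,
            "chondroitin": 0.15,
            "glucosamine+chondroitin": 0.10,
            "celecoxib": 0.09,
        },
        "tau": 0.08,
    },
    "withdrawal_ae": {
        "d": {
            "glucosamine": math.log(0.86),
            "chondroitin": math.log(1.33),
            "glucosamine+chondroitin": math.log(1.01),
            "celecoxib": math.log(1.04),
        },
        "tau": 0.15,
    },
    "serious_ae": {
        "d": {
            "glucosamine": math.log(1.03),
            "chondroitin": math.log(1.46),
            "glucosamine+chondroitin": math.log(1.07),
            "celecoxib": math.log(1.16),
        },
        "tau": 0.15,
    },
    "any_ae": {
        "d": {
            "glucosamine": math.log(1.12),
            "chondroitin": math.log(1.08),
            "glucosamine+chondroitin": math.log(1.01),
            "celecoxib": math.log(0.97),
        },
        "tau": 0.1,
    },
}
DEFAULT_TRUTH["specific_ae"] = DEFAULT_TRUTH["any_ae"]


@dataclass(frozen=True)
class SimulationScenario:
    outcome_kind: str
    d_true: dict[str, float]  # per non-placebo treatment, analysis scale
    tau: float
    designs: tuple[tuple[tuple[str, ...], int, int], ...] = DEFAULT_DESIGNS
    treatments: tuple[str, ...] = TREATMENTS
    baseline_mean_change: float = -1.5  # placebo-arm change on the 0-10 scale
    sd_change: float = 2.5  # change-score SD on the 0-10 scale
    scale_max_cycle: tuple[float, ...] = (10.0, 10.0, 10.0, 10.0, 100.0)
    baseline_risk: float = 0.15  # adverse-event risk in a baseline arm
    baseline_logit_sd: float = 0.3
    jsw_baseline_narrowing: float = 0.30  # mm over follow-up in a baseline arm
    jsw_sd: float = 0.45  # mm
    poor_quality_fraction: float = 13.0 / 54.0
    commercial_support_fraction: float = 43.0 / 54.0
    severe_pain_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)  # yes, no, unknown
    seed: int = 20151118

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if not 0 < self.baseline_risk < 1:
            raise ValueError("baseline_risk must be in (0, 1)")
        nodes = {t for design, _, _ in self.designs for t in design}
        import networkx as nx

        g = nx.Graph()
        for design, _, _ in self.designs:
            for i in range(len(design)):
                for j in range(i + 1, len(design)):
                    g.add_edge(design[i], design[j])
        if nodes and not nx.is_connected(g):
            raise ValueError("scenario design implies a disconnected network")

    @property
    def n_trials(self) -> int:
        return sum(reps for _, reps, _ in self.designs)

    def d_vector(self) -> dict[str, float]:
        out = {t: 0.0 for t in self.treatments}
        out.update(self.d_true)
        return out


def default_scenario(outcome_kind: str = "pain_smd") -> SimulationScenario:
    """The packaged 54-trial scenario (five connected nodes, placebo hub,
    ~16,700 patients) with truth values per :data:`DEFAULT_TRUTH`."""
    truth = DEFAULT_TRUTH[outcome_kind]
    return SimulationScenario(outcome_kind=outcome_kind, d_true=dict(truth["d"]), tau=truth["tau"])


def _expand_designs(scn: SimulationScenario) -> list[tuple[str, tuple[str, ...], int]]:
    trials = []
    idx = 1
    for design, reps, n_per_arm in scn.designs:
        ordered = tuple(sorted(design, key=lambda t: TREATMENT_INDEX[t]))
        for _ in range(reps):
            trials.append((f"T{idx:02d}", ordered, n_per_arm))
            idx += 1
    return trials


def _exact_count_flags(rng: np.random.Generator, n: int, count: int) -> np.ndarray:
    chosen = rng.permutation(n)[:count]
    mask = np.zeros(n, dtype=bool)
    mask[chosen] = True
    return mask


def generate_network(
    scn: SimulationScenario, seed: int | None = None
) -> tuple[NetworkDataset, dict]:
    """Simulate one dataset from the scenario; returns (dataset, truth).

    The truth dict records the basic parameters, tau, every trial's sampled
    deltas and the sensitivity flags, and is JSON-serializable.
    """
    rng = np.random.default_rng(scn.seed if seed is None else seed)
    family = outcome_family(scn.outcome_kind)
    d = scn.d_vector()
    layout = _expand_designs(scn)
    T = len(layout)

    poor = _exact_count_flags(rng, T, int(round(scn.poor_quality_fraction * T)))
    support = _exact_count_flags(rng, T, int(round(scn.commercial_support_fraction * T)))
    f_yes, f_no, _ = scn.severe_pain_fractions
    severe = np.full(T, "unknown", dtype=object)
    perm = rng.permutation(T)
    n_yes, n_no = int(round(f_yes * T)), int(round(f_no * T))
    severe[perm[:n_yes]] = "yes"
    severe[perm[n_yes : n_yes + n_no]] = "no"

    trials = []
    deltas_truth: dict[str, dict[str, float]] = {}
    for i, (tid, design, n_per_arm) in enumerate(layout):
        baseline = design[0]
        others = design[1:]
        m = len(others)
        mu = np.array([d[t] - d[baseline] for t in others])
        if m and scn.tau > 0:
            cov = scn.tau**2 * exchangeable_corr(m)
            delta = rng.multivariate_normal(mu, cov)
        else:
            delta = mu.copy()
        deltas_truth[tid] = {t: float(delta[j]) for j, t in enumerate(others)}

        arms = []
        scale_max = scn.scale_max_cycle[i % len(scn.scale_max_cycle)]
        if family == "binary":
            alpha = logit(scn.baseline_risk) + rng.normal(0.0, scn.baseline_logit_sd)
        for j, treat in enumerate(design):
            n = n_per_arm
            dj = 0.0 if j == 0 else float(delta[j - 1])
            if family == "continuous":
                true_mean = scn.baseline_mean_change + dj * scn.sd_change
                obs_mean = true_mean + scn.sd_change / math.sqrt(n) * rng.standard_normal()
                obs_sd = scn.sd_change * math.sqrt(rng.chisquare(n - 1) / (n - 1))
                f = scale_max / 10.0
                arms.append(
                    TrialArm(
                        trial_id=tid,
                        treatment=treat,
                        n=n,
                        mean_change=obs_mean * f,
                        sd_change=obs_sd * f,
                        scale_max=scale_max,
                    )
                )
            elif family == "binary":
                p = float(expit(alpha + dj))
                events = int(rng.binomial(n, p))
                arms.append(TrialArm(trial_id=tid, treatment=treat, n=n, events=events))
            else:
                true_mean = scn.jsw_baseline_narrowing - dj
                obs_mean = true_mean + scn.jsw_sd / math.sqrt(n) * rng.standard_normal()
                obs_sd = scn.jsw_sd * math.sqrt(rng.chisquare(n - 1) / (n - 1))
                arms.append(
                    TrialArm(
                        trial_id=tid,
                        treatment=treat,
                        n=n,
                        mean_narrowing_mm=obs_mean,
                        sd_mm=obs_sd,
                    )
                )
        trials.append(
            Trial(
                trial_id=tid,
                arms=tuple(arms),
                quality_flag="poor" if poor[i] else "adequate",
                commercial_support="yes" if support[i] else "no",
                baseline_severe_pain=str(severe[i]),
            )
        )

    ds = NetworkDataset(trials=tuple(trials), outcome_kind=scn.outcome_kind)
    truth = {
        "outcome_kind": scn.outcome_kind,
        "treatments": list(scn.treatments),
        "d_true": {t: float(v) for t, v in d.items()},
        "tau": scn.tau,
        "deltas": deltas_truth,
        "n_trials": T,
        "total_n": ds.n_patients,
        "n_poor_quality": int(poor.sum()),
        "n_commercial_support": int(support.sum()),
        "n_severe_pain_yes": int((severe == "yes").sum()),
        "seed": int(scn.seed if seed is None else seed),
    }
    return ds, truth


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
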