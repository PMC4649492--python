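"""Relative-effect construction: Hedges' g, mean difference, log odds ratio.

Sign conventions follow the clinical reading of each outcome:

* pain / function change scores: a *negative* SMD favours the second
  treatment (larger improvement, i.e. a more negative change);
* joint-space width: a *positive* MD favours the second treatment (less
  narrowing, more retained cartilage);
* adverse events: log-OR > 0 means more events on the second treatment.

Multi-arm trials yield a contrast vector against the trial's canonical
baseline arm together with its covariance; contrasts sharing the baseline
arm are correlated through that arm's variance contribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import Trial, TrialArm

MEASURES = ("smd", "md", "log_or")


class DegenerateArmError(ValueError):
    """An arm cannot support the requested effect measure (zero SD, n < 2...)."""


@dataclass(frozen=True)
class ContrastEstimate:
    """A relative effect of ``treat_b`` versus ``treat_a`` with its variance."""

    trial_id: str
    treat_a: str
    treat_b: str
    measure: str
    estimate: float
    variance: float
    informative: bool = True  # False for double-zero binary trials

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if self.informative and not self.variance > 0:
            raise ValueError(f"trial {self.trial_id}: variance must be > 0")

    @property
    def se(self) -> float:
        return math.sqrt(self.variance)

    def reversed(self) -> "ContrastEstimate":
        return ContrastEstimate(
            trial_id=self.trial_id,
            treat_a=self.treat_b,
            treat_b=self.treat_a,
            measure=self.measure,
            estimate=-self.estimate,
            variance=self.variance,
            informative=self.informative,
        )


@dataclass(frozen=True)
class TrialContrasts:
    """Per-trial contrast vector versus the baseline arm, with covariance."""

    trial_id: str
    baseline: str
    contrasts: tuple[ContrastEstimate, ...]
    covariance: np.ndarray

    def __post_init__(self) -> None:
        m = len(self.contrasts)
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (m, m):
            raise ValueError("covariance dimension must match the contrast vector")
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ValueError("covariance must be positive definite")
        object.__setattr__(self, "covariance", cov)

    @property
    def estimates(self) -> np.ndarray:
        return np.array([c.estimate for c in self.contrasts])

    @property
    def treatments(self) -> tuple[str, ...]:
        return tuple(c.treat_b for c in self.contrasts)


def _require_continuous(arm: TrialArm) -> None:
    if arm.mean_change is None or arm.sd_change is None:
        raise DegenerateArmError(
            f"trial {arm.trial_id}, arm {arm.treatment}: continuous payload required"
        )


def hedges_g(arm_a: TrialArm, arm_b: TrialArm) -> ContrastEstimate:
    """Standardized mean difference of change scores with Hedges' small-sample
    correction J = 1 - 3/(4(n_a + n_b - 2) - 1).

    Variance uses the common large-sample form
    (n_a + n_b)/(n_a n_b) + g^2 / (2 (n_a + n_b)).
    """
    _require_continuous(arm_a)
    _require_continuous(arm_b)
    na, nb = arm_a.n, arm_b.n
    if na < 2 or nb < 2:
        raise DegenerateArmError(
            f"trial {arm_a.trial_id}: n >= 2 required in both arms for an SMD"
        )
    s_pooled = math.sqrt(
        ((na - 1) * arm_a.sd_change**2 + (nb - 1) * arm_b.sd_change**2) / (na + nb - 2)
    )
    if s_pooled == 0:
        raise DegenerateArmError(f"trial {arm_a.trial_id}: zero pooled SD")
    j = 1.0 - 3.0 / (4.0 * (na + nb - 2) - 1.0)
    g = j * (arm_b.mean_change - arm_a.mean_change) / s_pooled
    variance = (na + nb) / (na * nb) + g * g / (2.0 * (na + nb))
    return ContrastEstimate(
        trial_id=arm_a.trial_id,
        treat_a=arm_a.treatment,
        treat_b=arm_b.treatment,
        measure="smd",
        estimate=g,
        variance=variance,
    )


def mean_difference(arm_a: TrialArm, arm_b: TrialArm) -> ContrastEstimate:
    """Joint-space-width mean difference in mm, oriented so that a positive
    value means the second arm retained more joint space (narrowed less)."""
    for arm in (arm_a, arm_b):
        if arm.mean_narrowing_mm is None or arm.sd_mm is None:
            raise DegenerateArmError(
                f"trial {arm.trial_id}, arm {arm.treatment}: jsw payload required"
            )
    estimate = arm_a.mean_narrowing_mm - arm_b.mean_narrowing_mm
    variance = arm_a.sd_mm**2 / arm_a.n + arm_b.sd_mm**2 / arm_b.n
    return ContrastEstimate(
        trial_id=arm_a.trial_id,
        treat_a=arm_a.treatment,
        treat_b=arm_b.treatment,
        measure="md",
        estimate=estimate,
        variance=variance,
    )


def _corrected_cells(arm_a: TrialArm, arm_b: TrialArm) -> tuple[float, float, float, float]:
    ea, fa = float(arm_a.events), float(arm_a.n - arm_a.events)
    eb, fb = float(arm_b.events), float(arm_b.n - arm_b.events)
    if min(ea, fa, eb, fb) == 0.0:
        ea, fa, eb, fb = ea + 0.5, fa + 0.5, eb + 0.5, fb + 0.5
    return ea, fa, eb, fb


def log_odds_ratio(arm_a: TrialArm, arm_b: TrialArm) -> ContrastEstimate:
    """Log odds ratio of events, second arm versus first, with a +0.5
    continuity correction to all four cells whenever any cell is zero.

    Double-zero trials are returned flagged non-informative: they carry no
    information for contrast-based pooling but are retained by the binomial
    NMA likelihood, which needs no correction.
    """
    for arm in (arm_a, arm_b):
        if arm.events is None:
            raise DegenerateArmError(
                f"trial {arm.trial_id}, arm {arm.treatment}: binary payload required"
            )
    informative = not (arm_a.events == 0 and arm_b.events == 0)
    ea, fa, eb, fb = _corrected_cells(arm_a, arm_b)
    estimate = math.log((eb * fa) / (ea * fb))
    variance = 1.0 / ea + 1.0 / fa + 1.0 / eb + 1.0 / fb
    return ContrastEstimate(
        trial_id=arm_a.trial_id,
        treat_a=arm_a.treatment,
        treat_b=arm_b.treatment,
        measure="log_or",
        estimate=estimate,
        variance=variance,
        informative=informative,
    )


_PAIRWISE = {"smd": hedges_g, "md": mean_difference, "log_or": log_odds_ratio}


def pairwise_contrast(arm_a: TrialArm, arm_b: TrialArm, measure: str) -> ContrastEstimate:
    try:
        fn = _PAIRWISE[measure]
    except KeyError:
        raise ValueError(f"unknown measure {measure!r}") from None
    return fn(arm_a, arm_b)


def _baseline_variance_share(baseline: TrialArm, measure: str) -> float:
    """Covariance between two contrasts sharing the baseline arm.

    Shared-baseline approximation: the baseline arm's own variance
    contribution — 1/n (SMD), sd^2/n (MD), 1/e + 1/(n-e) after correction
    (log-OR).
    """
    if measure == "smd":
        return 1.0 / baseline.n
    if measure == "md":
        return baseline.sd_mm**2 / baseline.n
    e = float(baseline.events)
    f = float(baseline.n - baseline.events)
    if e == 0.0 or f == 0.0:
        e, f = e + 0.5, f + 0.5
    return 1.0 / e + 1.0 / f


def trial_contrasts(trial: Trial, measure: str) -> TrialContrasts:
    """All non-baseline-vs-baseline contrasts of a trial with their covariance."""
    baseline = trial.arms[0]
    contrasts = tuple(pairwise_contrast(baseline, arm, measure) for arm in trial.arms[1:])
    m = len(contrasts)
    cov = np.empty((m, m))
    off = _baseline_variance_share(baseline, measure)
    cov.fill(off)
    for i, c in enumerate(contrasts):
        cov[i, i] = c.variance
    return TrialContrasts(
        trial_id=trial.trial_id,
        baseline=baseline.treatment,
        contrasts=contrasts,
        covariance=cov,
    )


def contrasts_table(trials, measure: str):
    """Flat per-trial contrast table (one row per baseline contrast)."""
    import pandas as pd

    rows = []
    for trial in trials:
        tc = trial_contrasts(trial, measure)
        for c in tc.contrasts:
            rows.append(
                {
                    "trial_id": c.trial_id,
                    "treat_a": c.treat_a,
                    "treat_b": c.treat_b,
                    "measure": c.measure,
                    "estimate": c.estimate,
                    "variance": c.variance,
                    "informative": c.informative,
                }
            )
    return pd.DataFrame(rows)
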