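"""Classical pairwise meta-analysis: DerSimonian-Laird random-effects pooling
with Cochran's Q / I-squared, and Begg's rank-correlation test for
publication bias."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .effects import ContrastEstimate

_Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class PooledResult:
    treat_a: str
    treat_b: str
    measure: str
    estimate: float
    ci_low: float
    ci_high: float
    se: float
    tau2: float
    Q: float
    df: int
    p_Q: float
    I2: float
    k: int

    @property
    def variance(self) -> float:
        return self.se**2

    @property
    def ratio_estimate(self) -> float:
        """Pooled OR when the analysis scale is log-odds."""
        if self.measure != "log_or":
            raise ValueError("ratio scale defined for log_or only")
        return math.exp(self.estimate)

    @property
    def ratio_ci(self) -> tuple[float, float]:
        if self.measure != "log_or":
            raise ValueError("ratio scale defined for log_or only")
        return math.exp(self.ci_low), math.exp(self.ci_high)


def _dl_core(y: np.ndarray, v: np.ndarray) -> dict:
    """DerSimonian-Laird moment estimator on estimates ``y`` with variances ``v``."""
    k = len(y)
    w = 1.0 / v
    sw = w.sum()
    ybar_fixed = float((w * y).sum() / sw)
    Q = float((w * (y - ybar_fixed) ** 2).sum())
    df = k - 1
    if df > 0:
        denom = sw - (w**2).sum() / sw
        tau2 = max(0.0, (Q - df) / denom)
        p_Q = float(stats.chi2.sf(Q, df))
        I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    else:
        tau2, p_Q, I2 = 0.0, 1.0, 0.0
    w_re = 1.0 / (v + tau2)
    est = float((w_re * y).sum() / w_re.sum())
    se = float(math.sqrt(1.0 / w_re.sum()))
    return {
        "estimate": est,
        "se": se,
        "tau2": tau2,
        "Q": Q,
        "df": df,
        "p_Q": p_Q,
        "I2": I2,
        "k": k,
        "fixed_estimate": ybar_fixed,
        "fixed_weight_sum": sw,
    }


def pool_dersimonian_laird(contrasts: list[ContrastEstimate]) -> PooledResult:
    """Random-effects pool of one comparison's per-trial contrasts.

    Non-informative (double-zero) contrasts are dropped before pooling.
    """
    usable = [c for c in contrasts if c.informative]
    if not usable:
        raise ValueError("no informative contrasts to pool")
    measures = {c.measure for c in usable}
    comparisons = {(c.treat_a, c.treat_b) for c in usable}
    if len(measures) != 1:
        raise ValueError(f"mixed measures: {sorted(measures)}")
    if len(comparisons) != 1:
        raise ValueError(f"mixed comparisons: {sorted(comparisons)}")
    y = np.array([c.estimate for c in usable])
    v = np.array([c.variance for c in usable])
    core = _dl_core(y, v)
    (treat_a, treat_b), (measure,) = comparisons.pop(), measures
    return PooledResult(
        treat_a=treat_a,
        treat_b=treat_b,
        measure=measure,
        estimate=core["estimate"],
        ci_low=core["estimate"] - _Z975 * core["se"],
        ci_high=core["estimate"] + _Z975 * core["se"],
        se=core["se"],
        tau2=core["tau2"],
        Q=core["Q"],
        df=core["df"],
        p_Q=core["p_Q"],
        I2=core["I2"],
        k=core["k"],
    )


@dataclass(frozen=True)
class BeggResult:
    kendall_tau: float
    p_value: float
    k: int
    method: str  # "exact" or "normal"


def _kendall_tau_b(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected Kendall rank correlation (tau-b)."""
    n = len(x)
    concordant_minus_discordant = 0
    for i in range(n):
        dx = np.sign(x[i + 1 :] - x[i])
        dy = np.sign(y[i + 1 :] - y[i])
        concordant_minus_discordant += int((dx * dy).sum())
    n0 = n * (n - 1) // 2
    tx = sum(c * (c - 1) // 2 for c in _tie_counts(x))
    ty = sum(c * (c - 1) // 2 for c in _tie_counts(y))
    denom = math.sqrt((n0 - tx) * (n0 - ty))
    if denom == 0:
        return 0.0
    return concordant_minus_discordant / denom


def _tie_counts(x: np.ndarray):
    _, counts = np.unique(x, return_counts=True)
    return counts


def begg_test(contrasts: list[ContrastEstimate], exact_max_k: int = 8) -> BeggResult:
    """Begg-Mazumdar rank-correlation test for funnel-plot asymmetry.

    Correlates the variance-standardized deviates
    (y_i - ybar_fixed) / sqrt(v_i - 1/sum(w)) with the variances v_i using
    Kendall's tau-b. The two-sided p-value comes from exhaustive permutation
    for k <= ``exact_max_k`` and from the tie-corrected normal approximation
    otherwise.
    """
    usable = [c for c in contrasts if c.informative]
    k = len(usable)
    if k < 3:
        raise ValueError(f"Begg's test requires at least 3 studies, got {k}")
    y = np.array([c.estimate for c in usable])
    v = np.array([c.variance for c in usable])
    w = 1.0 / v
    ybar = (w * y).sum() / w.sum()
    v_star = v - 1.0 / w.sum()
    # v_star > 0 whenever k >= 2 and variances are finite
    deviates = (y - ybar) / np.sqrt(v_star)
    tau_obs = _kendall_tau_b(deviates, v)

    if k <= exact_max_k:
        count = 0
        total = 0
        for perm in itertools.permutations(range(k)):
            t = _kendall_tau_b(deviates[list(perm)], v)
            if abs(t) >= abs(tau_obs) - 1e-12:
                count += 1
            total += 1
        return BeggResult(kendall_tau=tau_obs, p_value=count / total, k=k, method="exact")

    res = stats.kendalltau(deviates, v, method="asymptotic")
    return BeggResult(kendall_tau=tau_obs, p_value=float(res.pvalue), k=k, method="normal")
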