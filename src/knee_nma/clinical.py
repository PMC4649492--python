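"""Back-transformation of pooled SMDs to clinical scales and evaluation of
clinical significance of absolute within-group changes.

Pain SMDs back-transform to cm on a 0-10 visual analogue scale using a
median pooled SD of 2.5 cm; function SMDs to standardized WOMAC function
units (0-10 scale) using a median pooled SD of 2.1 units. An absolute
within-group change of at least 2 points on the 0-10 scale, in the
improving (negative) direction, counts as clinically significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import TrialArm
from .pairwise import _Z975, _dl_core

POOLED_SD = {"pain": 2.5, "function": 2.1}
UNITS = {"pain": "cm (0-10 VAS)", "function": "units (0-10 standardized WOMAC)"}
CLINICAL_THRESHOLD = 2.0


@dataclass(frozen=True)
class ClinicalEffect:
    outcome: str
    smd: float
    smd_ci_low: float
    smd_ci_high: float
    value: float
    ci_low: float
    ci_high: float
    pooled_sd_used: float
    units: str


def back_transform(
    smd: float, ci: tuple[float, float], outcome: str
) -> ClinicalEffect:
    """Multiply an SMD and its CI bounds by the outcome's median pooled SD."""
    if outcome not in POOLED_SD:
        raise ValueError(f"outcome must be one of {sorted(POOLED_SD)}, got {outcome!r}")
    sd = POOLED_SD[outcome]
    lo, hi = ci
    return ClinicalEffect(
        outcome=outcome,
        smd=smd,
        smd_ci_low=lo,
        smd_ci_high=hi,
        value=smd * sd,
        ci_low=lo * sd,
        ci_high=hi * sd,
        pooled_sd_used=sd,
        units=UNITS[outcome],
    )


@dataclass(frozen=True)
class AbsoluteChange:
    treatment: str
    estimate: float  # pooled mean change on the 0-10 scale
    ci_low: float
    ci_high: float
    k: int
    tau2: float


def pooled_absolute_change(arms: list[TrialArm]) -> AbsoluteChange:
    """Random-effects pool of single-arm mean changes, rescaled to 0-10.

    Each arm's mean change is rescaled by 10/scale_max; its variance is the
    rescaled sd^2 / n. The DerSimonian-Laird machinery is reused with the
    single-arm means playing the role of study estimates.
    """
    if not arms:
        raise ValueError("no arms to pool")
    treatments = {a.treatment for a in arms}
    if len(treatments) != 1:
        raise ValueError(f"arms from multiple treatments: {sorted(treatments)}")
    y, v = [], []
    for arm in arms:
        if arm.scale_max is None or arm.mean_change is None or arm.sd_change is None:
            raise ValueError(f"trial {arm.trial_id}: continuous payload with scale_max required")
        f = 10.0 / arm.scale_max
        y.append(arm.mean_change * f)
        v.append((arm.sd_change * f) ** 2 / arm.n)
    core = _dl_core(np.array(y), np.array(v))
    return AbsoluteChange(
        treatment=treatments.pop(),
        estimate=core["estimate"],
        ci_low=core["estimate"] - _Z975 * core["se"],
        ci_high=core["estimate"] + _Z975 * core["se"],
        k=core["k"],
        tau2=core["tau2"],
    )


def clinical_significance(pooled_change: float, threshold: float = CLINICAL_THRESHOLD) -> bool:
    """True iff the pooled within-group change reaches the threshold in the
    improving (negative) direction; the boundary itself counts. Worsening
    changes never qualify."""
    return pooled_change <= -threshold
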