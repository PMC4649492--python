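"""Loop inconsistency by the Bucher method.

For each closed triangle of direct evidence the target edge's direct
estimate is compared with the indirect estimate obtained by signed addition
of the other two edges (variances summing). The inconsistency factor
IF = |direct - indirect| gets a normal-theory 95% CI; on the log-odds scale
it exponentiates to the ratio of odds ratios (RoR >= 1 by orientation).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from scipy import stats

from .data import TREATMENT_INDEX, NetworkDataset
from .pairwise import PooledResult, pool_dersimonian_laird

_Z975 = stats.norm.ppf(0.975)


class MissingEdgeError(KeyError):
    def __init__(self, edge: tuple[str, str]):
        self.edge = edge
        super().__init__(f"no pooled direct estimate for edge {edge[0]} - {edge[1]}")


@dataclass(frozen=True)
class LoopAssessment:
    loop: tuple[str, ...]
    target_edge: tuple[str, str]
    direct: float
    direct_variance: float
    indirect: float
    indirect_variance: float
    inconsistency: float  # IF = |direct - indirect|
    if_variance: float
    if_ci_low: float
    if_ci_high: float
    ror: float | None  # ratio of odds ratios, log-OR measure only
    ror_ci_low: float | None
    ror_ci_high: float | None
    significant: bool


def enumerate_loops(ds: NetworkDataset) -> list[tuple[str, str, str]]:
    """All triangles of the evidence graph (every edge backed by >= 1 trial),
    each ordered canonically; the list is sorted deterministically."""
    g = ds.graph()
    nodes = sorted(g.nodes, key=lambda t: TREATMENT_INDEX[t])
    loops = []
    for a, b, c in itertools.combinations(nodes, 3):
        if g.has_edge(a, b) and g.has_edge(b, c) and g.has_edge(a, c):
            loops.append((a, b, c))
    return loops


def _oriented(edge_estimates: dict, a: str, b: str) -> tuple[float, float]:
    """Pooled estimate of b versus a, flipping a stored canonical edge if
    needed."""
    if (a, b) in edge_estimates:
        e = edge_estimates[(a, b)]
        return e.estimate, e.variance
    if (b, a) in edge_estimates:
        e = edge_estimates[(b, a)]
        return -e.estimate, e.variance
    key = tuple(sorted((a, b), key=lambda t: TREATMENT_INDEX[t]))
    raise MissingEdgeError(key)


def bucher_loop(
    loop: tuple[str, str, str],
    edge_estimates: dict[tuple[str, str], PooledResult],
    target_edge: tuple[str, str] | None = None,
) -> LoopAssessment:
    """Assess one triangle.

    ``edge_estimates`` maps ordered treatment pairs to pooled direct
    estimates (second treatment versus first). The inconsistency factor of a
    triangle does not depend on which edge is designated the target; the
    default target is the canonical first pair.
    """
    a, b, c = loop
    if target_edge is None:
        target_edge = (a, b)
    ta, tb = target_edge
    (other,) = [t for t in loop if t not in target_edge]
    direct, v_direct = _oriented(edge_estimates, ta, tb)
    # indirect path: ta -> other -> tb
    e1, v1 = _oriented(edge_estimates, ta, other)
    e2, v2 = _oriented(edge_estimates, other, tb)
    indirect, v_indirect = e1 + e2, v1 + v2
    diff = direct - indirect
    if_value = abs(diff)
    if_var = v_direct + v_indirect
    se = math.sqrt(if_var)
    lo, hi = if_value - _Z975 * se, if_value + _Z975 * se
    measure = edge_estimates[next(iter(edge_estimates))].measure
    is_ratio = measure == "log_or"
    return LoopAssessment(
        loop=loop,
        target_edge=target_edge,
        direct=direct,
        direct_variance=v_direct,
        indirect=indirect,
        indirect_variance=v_indirect,
        inconsistency=if_value,
        if_variance=if_var,
        if_ci_low=lo,
        if_ci_high=hi,
        ror=math.exp(if_value) if is_ratio else None,
        ror_ci_low=math.exp(lo) if is_ratio else None,
        ror_ci_high=math.exp(hi) if is_ratio else None,
        significant=lo > 0.0,
    )


def pool_direct_edges(ds: NetworkDataset, measure: str) -> dict[tuple[str, str], PooledResult]:
    """DerSimonian-Laird pooled direct estimate per evidence-graph edge, keyed
    by the canonical ordered pair. Multi-arm trials contribute the pairwise
    contrast of the two edge treatments."""
    per_edge: dict[tuple[str, str], list] = {}
    for trial in ds.trials:
        arms = {a.treatment: a for a in trial.arms}
        for ta, tb in itertools.combinations(trial.treatments, 2):
            key = tuple(sorted((ta, tb), key=lambda t: TREATMENT_INDEX[t]))
            from .effects import pairwise_contrast

            contrast = pairwise_contrast(arms[key[0]], arms[key[1]], measure)
            if contrast.informative:
                per_edge.setdefault(key, []).append(contrast)
    return {key: pool_dersimonian_laird(cs) for key, cs in per_edge.items() if cs}


def assess_loops(ds: NetworkDataset, measure: str) -> list[LoopAssessment]:
    """Enumerate triangles and run the Bucher comparison on each."""
    edges = pool_direct_edges(ds, measure)
    return [bucher_loop(loop, edges) for loop in enumerate_loops(ds)]
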