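"""Treatment rankings from posterior draws: rank probabilities, probability
of being best, and the surface under the cumulative ranking curve (SUCRA).

SUCRA summarizes a treatment's whole rank distribution on [0, 1]: a
treatment ranked first in every draw has SUCRA 1 (reported 100%), one ranked
last in every draw has SUCRA 0. Equivalently SUCRA = (K - mean rank)/(K - 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DIRECTIONS = ("lower_is_better", "higher_is_better")


@dataclass(frozen=True)
class RankingSummary:
    treatments: tuple[str, ...]
    direction: str
    rank_probabilities: np.ndarray  # (K, K): P(treatment k has rank j+1)
    cumulative: np.ndarray  # (K, K): P(rank <= j+1)
    sucra: np.ndarray  # (K,)
    prob_best: np.ndarray  # (K,)
    mean_rank: np.ndarray  # (K,)

    def to_frame(self) -> pd.DataFrame:
        k = len(self.treatments)
        df = pd.DataFrame(
            self.rank_probabilities,
            index=self.treatments,
            columns=[f"rank_{j + 1}" for j in range(k)],
        )
        df["prob_best"] = self.prob_best
        df["mean_rank"] = self.mean_rank
        df["sucra"] = self.sucra
        df["sucra_pct"] = np.round(100.0 * self.sucra).astype(int)
        return df


def rank_draws(draws, direction: str) -> RankingSummary:
    """Rank treatments per posterior draw and summarize.

    ``draws`` is either a :class:`~knee_nma.nma.PosteriorDraws` or a raw
    (n_draws, K) array of per-draw treatment effects (reference column
    included, on the analysis scale). With ``lower_is_better`` the smallest
    effect gets rank 1 (pain/function SMD); ``higher_is_better`` reverses
    this (joint-space-width MD). Exact ties are broken by the treatment-axis
    order, which follows the canonical treatment ordering.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if hasattr(draws, "pooled_d"):
        values = draws.pooled_d()
        treatments = tuple(draws.treatments)
    else:
        values = np.asarray(draws, dtype=float)
        treatments = tuple(f"treatment_{i}" for i in range(values.shape[1]))
    if values.ndim != 2:
        raise ValueError("draws must be 2-D (n_draws, K)")
    n, K = values.shape
    if K < 2:
        raise ValueError("ranking requires at least 2 treatments")
    if n == 0:
        raise ValueError("no draws")

    keyed = values if direction == "lower_is_better" else -values
    order = np.argsort(keyed, axis=1, kind="stable")  # order[:, j] = treatment ranked j+1

    P = np.empty((K, K))
    for j in range(K):
        P[:, j] = np.bincount(order[:, j], minlength=K) / n
    cum = np.cumsum(P, axis=1)
    sucra = cum[:, : K - 1].mean(axis=1)
    mean_rank = P @ (np.arange(K) + 1.0)
    return RankingSummary(
        treatments=treatments,
        direction=direction,
        rank_probabilities=P,
        cumulative=cum,
        sucra=sucra,
        prob_best=P[:, 0],
        mean_rank=mean_rank,
    )


def direction_for_outcome(outcome_kind: str) -> str:
    """Default ranking direction per outcome: improvement is a more negative
    change score (pain/function) or larger odds reduction, but a *larger*
    retained joint-space width."""
    return "higher_is_better" if outcome_kind == "jsw_md" else "lower_is_better"
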