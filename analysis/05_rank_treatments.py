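#!/usr/bin/env python
"""Rank treatments by SUCRA for pain relief: rank probabilities, probability
of being best, and the surface under the cumulative ranking curve."""

from pathlib import Path

from knee_nma.data import read_dataset
from knee_nma.nma import McmcConfig, build_model, run_mcmc
from knee_nma.ranking import direction_for_outcome, rank_draws

SEED = 20250926
root = Path(__file__).resolve().parent.parent / "results"

ds = read_dataset(root / "data" / "pain_smd.csv", "pain_smd")
draws = run_mcmc(
    build_model(ds), McmcConfig(n_chains=3, n_iter=12_000, n_burn=2_000, base_seed=SEED)
)
summary = rank_draws(draws, direction_for_outcome("pain_smd"))
frame = summary.to_frame()
frame.to_csv(root / "sucra_pain.csv")

print("pain relief ranking (lower SMD is better):")
for t in frame.sort_values("sucra", ascending=False).itertuples():
    print(f"  {t.Index:>24s}: SUCRA {t.sucra_pct:3d}%  P(best) {t.prob_best:.2f}  "
          f"mean rank {t.mean_rank:.2f}")
print(f"\nwrote {root / 'sucra_pain.csv'}")
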