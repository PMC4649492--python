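#!/usr/bin/env python
"""Classical pairwise meta-analysis of every direct comparison: DL pooled
effects, Q / I-squared heterogeneity, and Begg's publication-bias test —
for the pain outcome and the adverse-event (withdrawal) outcome."""

from pathlib import Path

from knee_nma.data import read_dataset
from knee_nma.pipeline import _pairwise_table

root = Path(__file__).resolve().parent.parent / "results"

for outcome, measure in (("pain_smd", "smd"), ("withdrawal_ae", "log_or")):
    ds = read_dataset(root / "data" / f"{outcome}.csv", outcome)
    table = _pairwise_table(ds, measure)
    out = root / f"pairwise_{outcome}.csv"
    table.to_csv(out, index=False)
    print(f"\n{outcome}: {len(table)} direct comparisons")
    heterogeneous = table[table.I2 >= 50]
    print(f"  comparisons with I2 >= 50%: {len(heterogeneous)}")
    if "begg_p" in table:
        biased = table[table.begg_p <= 0.05]
        print(f"  comparisons with Begg p <= 0.05: {len(biased.dropna(subset=['begg_p']))}")
    print(f"  wrote {out}")
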