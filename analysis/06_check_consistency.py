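#!/usr/bin/env python
"""Bucher loop-inconsistency assessment: for every closed triangle of direct
evidence, compare the pooled direct estimate of one edge with the indirect
estimate along the other two edges. On the adverse-event (log-odds) scale
the inconsistency factor exponentiates to a ratio of odds ratios."""

from pathlib import Path

import pandas as pd

from knee_nma.data import read_dataset
from knee_nma.inconsistency import assess_loops

root = Path(__file__).resolve().parent.parent / "results"

for outcome, measure in (("pain_smd", "smd"), ("withdrawal_ae", "log_or")):
    ds = read_dataset(root / "data" / f"{outcome}.csv", outcome)
    rows = []
    for la in assess_loops(ds, measure):
        rows.append(
            {
                "loop": "/".join(la.loop),
                "target_edge": "-".join(la.target_edge),
                "direct": la.direct,
                "indirect": la.indirect,
                "IF": la.inconsistency,
                "if_ci_low": la.if_ci_low,
                "if_ci_high": la.if_ci_high,
                "RoR": la.ror,
                "ror_ci_low": la.ror_ci_low,
                "ror_ci_high": la.ror_ci_high,
                "significant": la.significant,
            }
        )
    df = pd.DataFrame(rows)
    out = root / f"loops_{outcome}.csv"
    df.to_csv(out, index=False)
    n_sig = int(df.significant.sum())
    print(f"{outcome}: {len(df)} loops assessed, {n_sig} with significant inconsistency")
    worst = df.loc[df.IF.idxmax()]
    print(f"  largest IF: {worst.loop} ({worst.IF:.3f}, CI {worst.if_ci_low:.3f} to {worst.if_ci_high:.3f})")
    print(f"  wrote {out}")
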