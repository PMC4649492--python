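#!/usr/bin/env python
"""Generate the synthetic evidence base: the packaged 54-trial five-treatment
knee-OA network under each outcome kind, with its truth files.

Writes results/data/<outcome>.csv and matching truth JSONs. Every later step
reads these files, so the whole analysis is reproducible from this seed.
"""

from pathlib import Path

from knee_nma.data import write_dataset
from knee_nma.simulate import default_scenario, generate_network, write_truth

SEED = 20250926
OUTCOMES = ("pain_smd", "function_smd", "jsw_md", "withdrawal_ae", "serious_ae", "any_ae")

outdir = Path(__file__).resolve().parent.parent / "results" / "data"
outdir.mkdir(parents=True, exist_ok=True)

for outcome in OUTCOMES:
    scn = default_scenario(outcome)
    ds, truth = generate_network(scn, seed=SEED)
    write_dataset(ds, outdir / f"{outcome}.csv")
    write_truth(truth, outdir / f"{outcome}_truth.json")
    print(
        f"{outcome}: {ds.n_trials} trials, {ds.n_patients} patients, "
        f"tau = {truth['tau']}, {truth['n_poor_quality']} poor-quality trials"
    )

print(f"\nwrote datasets and truth files to {outdir}")
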