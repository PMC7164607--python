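"""Process raw qPCR Cq data: replicate collapsing, standard curves, quantities.

Simulates a triplicate qPCR experiment with fivefold-dilution standard
curves, collapses technical replicates with the 0.5-cycle outlier rule, fits
per-gene standard curves, and converts mean Cq to relative quantities.
"""

import pandas as pd

from refstab import collapse_table, fit_curves_from_table, quantify_table, simulate_cq
from refstab.simulate import default_fixture_cq_spec

dataset, truth = simulate_cq(default_fixture_cq_spec(seed=42))

collapsed = collapse_table(dataset.cq_long)
n_discard = int(collapsed["outlier_discarded"].sum())
n_failed = int(collapsed["failed"].sum())
print(f"{len(collapsed)} reactions collapsed; "
      f"{n_discard} had one replicate discarded (>0.5 Cq from both others), "
      f"{n_failed} failed outright")

curves = fit_curves_from_table(dataset.dilutions)
rows = [
    {"gene": g, "slope": c.slope, "r2": c.r_squared,
     "efficiency_%": c.efficiency_percent}
    for g, c in list(curves.items())[:5]
]
print("\nStandard curves (first 5 genes; slope ~ -3.32 means 100% efficiency):")
print(pd.DataFrame(rows).round(3).to_string(index=False))

rq = quantify_table(collapsed, curves)
print("\nRelative quantities for gene P1 (vs the undiluted curve reference):")
print(rq[rq["gene_id"] == "P1"][["sample_id", "mean_cq", "quantity"]]
      .round(4).to_string(index=False))
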