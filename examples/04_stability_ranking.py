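"""Rank candidate reference genes by stability with four algorithms.

Builds a mean-Cq matrix for 9 candidates plus an unstable UBQ-like gene,
runs delta-Ct, BestKeeper, NormFinder and geNorm on the raw Cq values
(fixed efficiency 2.0), and combines the four ranks into a comprehensive
geometric-mean rank. Lower stability values and ranks = more stable.
"""

from refstab import simulate_cq, stability_report
from refstab.simulate import default_fixture_cq_spec

dataset, truth = simulate_cq(default_fixture_cq_spec(seed=42))
ranking_genes = [f"P{i}" for i in range(1, 10)] + ["UBQ"]
cq_matrix = dataset.mean_cq_matrix().loc[ranking_genes]

report = stability_report(cq_matrix)
cols = ["deltact_value", "bestkeeper_value", "normfinder_value", "genorm_m",
        "comprehensive_geomean", "comprehensive_rank"]
print(report[cols].sort_values("comprehensive_rank").round(3).to_string())
print()
order = report.sort_values("comprehensive_rank").index
print("Comprehensive ranking:", " > ".join(order))
print("True per-gene Cq noise (cycles) — the ranking should track it:")
print(truth.genes.loc[ranking_genes, "noise_sd"].round(3).to_string())
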