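"""Run the three-stage candidate reference-gene cascade on synthetic data.

Stable genes must show a small fold change between genotype groups, a mean
expression inside the qPCR-friendly (11, 450) window, and low variability
relative to the stoneless endocarp reference library (score < 0.20, then
< 0.11).
"""

from refstab import CountSimSpec, FilterThresholds, run_cascade, simulate_counts, to_rpm

matrix, truth = simulate_counts(CountSimSpec(n_genes=200, seed=3))
rpm = to_rpm(matrix, "metadata")

thresholds = FilterThresholds(
    reference_library="L20",  # the stoneless endocarp library
    group_a=frozenset(rpm.libraries_where(genotype_group="stoneless")),
    group_b=frozenset(rpm.libraries_where(genotype_group="normal")),
)
trace = run_cascade(rpm, thresholds)
print("Survivors per stage (fold-change+window / score<0.20 / score<0.11):")
print("  %d / %d / %d of %d genes" % (*trace.counts, len(rpm.gene_ids)))

stable = set(truth.genes[truth.genes["class"] == "stable"].index)
recovered = stable & set(trace.survivors_stage3)
print(f"Planted stable genes recovered at stage 3: {len(recovered)}/{len(stable)}")
print("Top 5 by endocarp-relative stability score (lower = more stable):")
print(trace.scores.loc[trace.survivors_stage3[:5]].round(4).to_string())
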