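# refstab

Reference-gene discovery and stability ranking for expression studies.

Quantitative PCR (qPCR) expression measurements are only as reliable as the
reference genes used to normalize them: a "housekeeping" gene that drifts
across tissues or timepoints silently distorts every normalized profile.
`refstab` implements the complete workflow for mining an RNA-seq experiment
for candidate reference genes and validating them by qPCR, as practiced in
plant expression studies of early fruit development (whole ovary/fruit
timecourses plus endocarp — stone — tissue from normal and minimal-endocarp
genotypes):

1. **Expression summaries** (`refstab.matrix`) — gene-by-library matrices of
   unique read counts, reads-per-million (RPM) conversion, and the per-gene
   screening statistics: mean, StDev, high, low, high/low ratio and
   CV% = 100·σ/μ.
2. **Candidate filter cascade** (`refstab.filtering`) — three nested screens:
   between-group fold change fc = max(μ_A, μ_B)/min(μ_A, μ_B) within a
   narrow window (default [1.0, 1.1]) and mean expression inside a
   qPCR-friendly window (default (11, 450) RPM); then the endocarp-relative
   stability score σ(all libraries)/x(endocarp reference library) below
   0.20; then below 0.11. Fully traced per gene and per stage.
3. **qPCR Cq processing** (`refstab.qpcr`) — technical-triplicate collapsing
   with the 0.5-cycle outlier rule, standard curves Cq = b + m·log10(input)
   fitted on fivefold dilution series, amplification efficiency
   E% = 100·(10^(−1/m) − 1), and relative quantities Q = 10^((Cq−b)/m).
4. **Stability ranking** (`refstab.stability`) — four classical algorithms on
   raw mean Cq: comparative delta-Ct (mean pairwise StDev of Cq differences),
   BestKeeper (raw-Cq dispersion), NormFinder (two-way model residual
   variation, with an intra/intergroup mode), geNorm (mean pairwise-variation
   M with iterative elimination), plus the RefFinder-style comprehensive
   rank: the geometric mean of the four per-method ranks.
5. **Normalization** (`refstab.normalize`) — per-sample geometric-mean
   factors from any reference-gene combination and scheme comparisons for
   target genes.
6. **Synthetic data** (`refstab.simulate`) — negative-binomial count
   matrices on the 20-library two-genotype design and triplicate Cq
   experiments with shared sample effects, planted gene classes and full
   ground truth, so every stage is testable without external data.

## Worked example

Rank nine simulated candidate reference genes plus an unstable UBQ-like
gene (`examples/04_stability_ranking.py`):

```python
from refstab import simulate_cq, stability_report
from refstab.simulate import default_fixture_cq_spec

dataset, truth = simulate_cq(default_fixture_cq_spec(seed=42))
genes = [f"P{i}" for i in range(1, 10)] + ["UBQ"]
report = stability_report(dataset.mean_cq_matrix().loc[genes])
print(report.sort_values("comprehensive_rank").round(3))
```

prints (abridged):

```
     deltact_value  bestkeeper_value  normfinder_value  genorm_m  comprehensive_rank
P5           0.309             0.593             0.146     0.120                 1.0
P8           0.328             0.674             0.203     0.093                 2.0
P3           0.330             0.668             0.205     0.093                 3.0
...
UBQ          1.422             1.188             1.341     1.422                10.0
```

Each value is that method's instability measure in its own units (delta-Ct,
BestKeeper in cycles; NormFinder and geNorm M dimensionless on the log2
scale); lower is more stable. The planted high-noise UBQ-like gene (true Cq
noise 1.0 cycles vs ≤ 0.25 for the candidates) lands last under every
method and in the comprehensive rank — the qualitative outcome the whole
pipeline exists to deliver.

The other scripts in `examples/` walk through expression summaries, the
filter cascade, Cq processing and normalization-scheme comparison, each
printing what it computes and what the numbers mean.

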