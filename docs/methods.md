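# Methods

This note documents the models, estimators, numerical conventions and
design choices behind `refstab`, and what the synthetic benchmarks do and
do not demonstrate.

## Expression summaries and RPM

Counts are converted to reads per million as RPM_gl = 10⁶·c_gl/N_l, where
N_l is either the library's total mapped reads (metadata) or the matrix
column sum (in which case columns sum to 10⁶ exactly). Per-gene summaries
use the sample standard deviation (n−1 denominator) by default; the
population form is available via `ddof=0`. The choice is not detectable in
integer-rounded CV output at n = 20 but is exposed because screening
decisions can sit on a threshold. Report formatting rounds high/low ratios
to two decimals and CV% to integers, with exact halves rounded away from
zero; full precision is always retained internally.

A gene whose lowest value is zero has an undefined high/low ratio (reported
as missing, not infinity); a single-library subset has an undefined StDev.
Both are carried as explicit flags.

The two bundled summary tables (13 previously published Prunus reference
genes; 9 RNA-seq-derived candidates) are printed statistics, and printed
inputs are rounded. Recomputing CV% and the ratio from them therefore
reproduces the printed values only to within the propagated half-unit of
the inputs' last printed digits — exactly, where the inputs carry four
significant figures (all 13 CVs of the published table), and to ±1 in the
last digit where they are integer-rounded (the candidate table's CVs). The
acceptance checks encode precisely this propagated-rounding bound rather
than a loose global tolerance.

## Candidate filter cascade

The screen looks for genes that are (i) balanced between genotype groups,
(ii) expressed in a window convenient for qPCR, and (iii) quiet relative to
the tissue that motivates the screen.

* **Fold change**: fc_g = max(μ_A, μ_B)/min(μ_A, μ_B) ≥ 1 over pooled group
  means. The default window [1.0, 1.1] (closed bounds) admits at most a 10%
  group difference. A literal `abs_log2` mode — |log2 fc| within the window
  — is provided for comparison; it admits 2.0–2.14-fold changers and is not
  the default because such genes are the opposite of stable. Genes with
  both group means zero are undefined, one zero mean is flagged infinite;
  neither can pass a finite window.
* **Expression window**: overall mean strictly inside (11, 450) by default
  — high enough to detect reliably, low enough not to force extra cDNA
  dilution.
* **Endocarp-relative stability**: s_g = σ(values over all 20 libraries) /
  value in the designated endocarp reference library. Dividing by the
  endocarp value (rather than the mean) biases survival toward genes that
  hold their level in endocarp. Stage 2 keeps s < 0.20, stage 3 keeps
  s < 0.11, both strict. A zero reference value makes a gene unscorable and
  it is excluded.

Stage sets are nested by construction, invariant to input gene order, and
monotone in every threshold. Because stage 3's predicate implies stage 2's,
the stage-3 set equals applying the tighter cap in a single pass. Survivor
lists are ordered by ascending score with gene-id tie-breaks for
determinism.

## qPCR processing

* **Replicate collapsing**: with triplicates, a value more than 0.5 cycles
  from *both* others is discarded and the remaining two averaged; three
  mutually distant values fail the reaction (no mean, NaN downstream,
  never silently dropped). With two replicates the rule is inapplicable:
  both are averaged and flagged `unguarded`. The rule is permutation
  invariant, and at most one value can be an outlier (if two values are
  each far from both others, so is the third).
* **Standard curves**: ordinary least squares of mean Cq on log10(relative
  input), with the undiluted sample at 1.0 and a fivefold series at 1,
  1/5, 1/25, … (the axis convention is ours; only ratios of inputs matter
  for the slope). At least three distinct dilution points are required.
* **Efficiency**: E% = 100·(10^(−1/slope) − 1); −3.32 cycles/decade ≈ 100%.
* **Quantities**: Q = 10^((Cq − intercept)/slope), relative to the curve's
  undiluted reference; exact inverse of the curve on noiseless data.

Efficiency-corrected quantification is kept separate from stability
ranking, which deliberately consumes raw mean Cq at a fixed efficiency of
2.0 per cycle (per-gene efficiencies are accepted for sensitivity
analysis). This mirrors how comprehensive-ranking tools are commonly run.

## Stability algorithms

All methods operate on a complete genes × samples mean-Cq matrix (≥ 3 genes
and ≥ 3 samples for the full report); linearization uses
Q_gs = E^(min_s' Cq_gs' − Cq_gs), so each gene's best sample has quantity 1.

* **Comparative delta-Ct**: value_g = mean over partners h≠g of
  StDev_s(Cq_gs − Cq_hs), sample StDev throughout.
* **BestKeeper**: dispersion of raw Cq — mean absolute deviation about the
  mean by default, StDev optional. The original tool reports MAD about the
  gene's central Cq; the exact variant used inside comprehensive-ranking
  web tools is undocumented, so both are exposed. BestKeeper is the one
  method deliberately *not* invariant to per-sample shifts: raw-Cq
  dispersion includes input-amount variation.
* **NormFinder (ungrouped)**: on y = log2 Q, fit the additive two-way model
  y_gs = gene effect + sample effect + residual by double centering;
  value_g = StDev of gene g's residuals × √(g/(g−1)). The inflation factor
  compensates the fit absorbing 1/g of each gene's own variation; it is
  configurable because the published estimator family varies in this
  constant. Unit tests pin the estimator to its own residual definition.
* **NormFinder (grouped)**: sample effects are removed by column centering;
  for each gene and group, d_gk is the deviation of the gene's group mean
  from its overall level and σ_gk the intragroup residual StDev (inflated
  as above); value_g = mean_k(|d_gk| + σ_gk/√n_k). This is an
  intra/intergroup decomposition in the spirit of the published model-based
  method but without its shrinkage of group differences — a deliberate
  simplification, documented here, that preserves the ordering behaviour
  (group-divergent genes are heavily penalized) at small gene counts.
  Groups of one sample are rejected.
* **geNorm**: V_gh = StDev_s(log2(Q_gs/Q_hs)); M_g = mean_h≠g V_gh. The
  gene with the highest M is removed (ties: lexicographically last gene id,
  deterministic) and M recomputed until two genes remain; each gene reports
  the M from its last round of inclusion, so the final pair's M values both
  equal their mutual V. The final ranking is the reverse elimination order
  with the surviving pair sharing mid-rank 1.5 by default (a `split` mode
  assigns 1 and 2 by the pair's last multi-gene-round M). With all
  efficiencies at 2, the first-round M is algebraically identical to the
  delta-Ct value — a cross-validation identity the tests verify to 1e−10.
* **Pairwise variation V(k/k+1)**: StDev over samples of the log2 ratio of
  geometric-mean normalization factors from the top-k vs top-(k+1)
  geNorm-ranked genes. Computed, not adjudicated: no "use k references"
  recommendation is made.
* **Comprehensive rank**: geometric mean of the four per-method ranks
  (method ranks use mid-ranks on ties); final ordering by that score with
  ties broken by delta-Ct value, then gene id.

## Normalization

The per-sample factor for a reference set R is (∏_{r∈R} Q_rs)^{1/|R|},
computed in log space. Normalized target series are reported in relative
units without rescaling to a calibrator sample (the units are arbitrary
either way); a calibrator option divides the series by its value in a named
sample. Failed reactions propagate as missing values. Scaling every
reference by a constant c scales factors by c and divides normalized values
by c; schemes are invariant to reference order, and k copies of one gene
equal the single-gene scheme.

## Synthetic data

**Counts** follow a Gamma-Poisson (negative-binomial) model:
mean_gl = (library size_l/10⁶) · baseline_g · 2^(bias_g·[l is endocarp]),
with gene-level dispersion (0 degenerates to Poisson) — the standard
RNA-seq noise model. The default design is the 20-library layout above
with library sizes uniform on 5–20 million reads. Planted classes:
`stable` (bias 0, baselines 30–300, inside the screening window),
`tissue_biased` (endocarp log2 shift of 1–2.5 with random sign, emulating
reference genes that run higher or lower in endocarp) and `noisy` (extra
per-library log2 jitter, σ = 0.8). Baselines for non-stable genes span
10–500 so the expression window has genuine work to do. At these defaults
the cascade separates the classes essentially perfectly; the acceptance
benchmark reports the realized recovery rate over 20 simulated studies.

**Cq experiments**: Cq_gsr = intercept_g + slope_g·log10(q_gs) + δ_s +
ε_gs + η_gsr, where q_gs encodes an optional planted log2 expression
profile (flat for reference-like genes), δ_s ~ N(0, 0.8²) is a sample
effect shared by all genes (input-amount variation — precisely what
reference-gene normalization removes, which makes its benefit
demonstrable), ε_gs is per-gene biological noise and η_gsr ~ N(0, 0.1²)
replicate noise. Outliers are injected per reaction with a set probability
by shifting one replicate ±1.2 cycles (beyond the 0.5-cycle rule).
Dilution series are generated from the same curves with replicate noise
only. The default sample panel is a 7-point developmental series plus four
endocarp samples (11 total).

What the synthetic benchmarks do **not** show: real RNA-seq has correlated
genes, composition effects, mapping bias and batch structure; real qPCR
has inhibition, primer-dimer artifacts and non-Gaussian failure modes.
Passing tests demonstrate the estimators and the pipeline plumbing are
correct under the stated models, not that any particular biological gene
is stable.

## Benchmark problem sizes

The rank-recovery experiment uses 6 genes (three at σ = 0.1 cycles, three
at σ = 1.0) × 11 samples × 200 replicates — ample to resolve a 10-fold
noise separation while keeping the full suite fast. The cascade/brute-force
comparison uses 500 genes × 20 libraries with ~1% structural zeros, and
threshold monotonicity is probed over 50 random threshold settings on 300
genes. The observed recovery rates (≥ 98% for the top-3 rank recovery,
100% for planted filter classes) are computed at run time by the
acceptance script, never asserted as constants.

## Known limitations

* Cross-study normalization factors (TMM/median-of-ratios) are out of
  scope; only within-library RPM scaling is provided, and filter
  thresholds apply to whichever normalized layer is loaded.
* The grouped stability mode is a simplified decomposition (no shrinkage);
  for publication-grade grouped NormFinder values use the original
  implementation and compare.
* The comprehensive rank reproduces the geometric-mean-of-ranks recipe,
  not any specific web tool's tie-handling byte-for-byte.
* The final choice of which surviving candidates to assay by qPCR is a
  judgment call and is not modeled; the cascade emits the ranked survivor
  list.
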