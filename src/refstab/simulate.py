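"""Synthetic RNA-seq count matrices and qPCR experiments with known truth.

The generators emulate a 20-library stone-fruit early-development study —
two normal-stone cultivars and two minimal-endocarp ("stoneless") trees,
each contributing an ovary/whole-fruit timecourse plus one endocarp library
— and the follow-up qPCR design of a 7-point developmental series plus four
endocarp RNAs, assayed in technical triplicate with fivefold-dilution
standard curves.

Counts follow a negative-binomial (Gamma-Poisson) model; Cq values follow a
linear standard-curve model with shared per-sample effects (mimicking
input-RNA-amount variation, which is exactly what reference-gene
normalization removes), per-gene biological noise and per-replicate
technical noise, with optional injected replicate outliers. Every draw is
reproducible from the spec's seed, and a :class:`GroundTruth` labels every
simulated gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, LibraryMeta, write_matrix
from .qpcr import collapse_table

__all__ = [
    "CountSimSpec",
    "CqGeneSpec",
    "CqSimSpec",
    "CqDataset",
    "GroundTruth",
    "default_library_design",
    "default_cq_samples",
    "simulate_counts",
    "simulate_cq",
    "make_fixture_suite",
]


def default_library_design() -> list[LibraryMeta]:
    """The 20-library design: 4 trees x (4 fruit timepoints + 1 endocarp).

    Two normal-stone cultivars and two minimal-endocarp trees; libraries
    L05/L10/L15/L20 are the endocarp libraries, L20 the stoneless endocarp
    used as the filter cascade's reference library. Total mapped reads are
    design placeholders replaced by the simulator's drawn library sizes.
    """
    design = []
    trees = [
        ("CultivarA", "A1", "normal"),
        ("CultivarB", "B1", "normal"),
        ("Stoneless", "S1", "stoneless"),
        ("Stoneless", "S2", "stoneless"),
    ]
    lib = 0
    for cultivar, tree, group in trees:
        stages = [
            ("flower", "T1"),
            ("ovary", "T2"),
            ("whole_fruit", "T3"),
            ("whole_fruit", "T4"),
            ("endocarp", "T3"),
        ]
        for tissue, timepoint in stages:
            lib += 1
            design.append(
                LibraryMeta(
                    library_id=f"L{lib:02d}",
                    cultivar=cultivar,
                    tree=tree,
                    tissue=tissue,
                    timepoint=timepoint,
                    genotype_group=group,
                    total_mapped_reads=10_000_000,
                )
            )
    return design


@dataclass(frozen=True)
class CountSimSpec:
    """Negative-binomial count simulation with planted gene classes.

    Gene classes: ``stable`` (no tissue bias, baseline drawn inside the
    qPCR-friendly expression window, low noise), ``tissue_biased``
    (endocarp-specific log2 shift with random sign, emulating genes that run
    higher or lower in endocarp than in whole fruit) and ``noisy`` (extra
    per-library log-normal jitter). Fractions give stable and tissue-biased
    shares; the remainder is noisy.
    """

    n_genes: int = 500
    library_design: tuple[LibraryMeta, ...] = field(
        default_factory=lambda: tuple(default_library_design())
    )
    stable_fraction: float = 0.2
    tissue_biased_fraction: float = 0.3
    endocarp_log2_bias: tuple[float, float] = (1.0, 2.5)
    baseline_mean: tuple[float, float] = (10.0, 500.0)
    stable_baseline_mean: tuple[float, float] = (30.0, 300.0)
    noisy_log2_sd: float = 0.8
    dispersion: float = 0.002
    library_size: tuple[float, float] = (5e6, 2e7)
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.stable_fraction, self.tissue_biased_fraction):
            if not 0 <= f <= 1:
                raise ValueError("class fractions must be in [0, 1]")
        if self.stable_fraction + self.tissue_biased_fraction > 1:
            raise ValueError("class fractions must sum to <= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")


@dataclass
class GroundTruth:
    """Planted truth for a simulated dataset (one row per gene)."""

    genes: pd.DataFrame
    sample_effects: pd.Series | None = None


def simulate_counts(spec: CountSimSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw a raw-count matrix plus ground truth from a count spec.

    mean_gl = library_size_l / 1e6 * baseline_g * 2^(bias_g * endocarp_l)
    * jitter_gl, with counts ~ NegativeBinomial(mean, dispersion) via the
    Gamma-Poisson mixture (dispersion 0 degenerates to Poisson).
    """
    rng = np.random.default_rng(spec.seed)
    design = list(spec.library_design)
    n_lib = len(design)
    n = spec.n_genes
    n_stable = int(round(n * spec.stable_fraction))
    n_biased = int(round(n * spec.tissue_biased_fraction))
    n_noisy = n - n_stable - n_biased
    classes = ["stable"] * n_stable + ["tissue_biased"] * n_biased + ["noisy"] * n_noisy

    baselines = np.empty(n)
    baselines[:n_stable] = rng.uniform(*spec.stable_baseline_mean, size=n_stable)
    baselines[n_stable:] = rng.uniform(*spec.baseline_mean, size=n - n_stable)
    biases = np.zeros(n)
    lo, hi = spec.endocarp_log2_bias
    signs = rng.choice([-1.0, 1.0], size=n_biased)
    biases[n_stable : n_stable + n_biased] = signs * rng.uniform(lo, hi, size=n_biased)
    noise_sd = np.zeros(n)
    noise_sd[n_stable + n_biased :] = spec.noisy_log2_sd

    lib_sizes = rng.uniform(*spec.library_size, size=n_lib)
    endocarp = np.array([1.0 if m.tissue == "endocarp" else 0.0 for m in design])

    mu = (
        (lib_sizes / 1e6)[None, :]
        * baselines[:, None]
        * 2.0 ** (biases[:, None] * endocarp[None, :])
    )
    jitter_sd = noise_sd[:, None] * np.ones((1, n_lib))
    mu = mu * 2.0 ** (rng.normal(0.0, 1.0, size=mu.shape) * jitter_sd)
    if spec.dispersion > 0:
        lam = rng.gamma(shape=1.0 / spec.dispersion, scale=mu * spec.dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam)

    gene_ids = [f"G{i + 1:04d}" for i in range(n)]
    design = [replace(m, total_mapped_reads=int(s)) for m, s in zip(design, lib_sizes)]
    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=[m.library_id for m in design]),
        design,
        "raw_counts",
    )
    truth = GroundTruth(
        genes=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "class": classes,
                "baseline_mean": baselines,
                "endocarp_log2_bias": biases,
                "noise_log2_sd": noise_sd,
            }
        ).set_index("gene_id")
    )
    return matrix, truth


def default_cq_samples() -> tuple[str, ...]:
    """A 7-point developmental series plus four endocarp RNAs (11 samples)."""
    return (
        "DS1", "DS2", "DS3", "DS4", "DS5", "DS6", "DS7",
        "Cendo1", "Cendo2", "Stendo1", "Stendo2",
    )


@dataclass(frozen=True)
class CqGeneSpec:
    """True parameters of one simulated qPCR assay.

    ``noise_sd`` is the gene's biological Cq noise (cycles); ``efficiency``
    the per-cycle amplification fold (2.0 = 100%); ``log2_profile`` an
    optional per-sample log2 expression profile (None = flat, the
    reference-gene case).
    """

    gene_id: str
    noise_sd: float = 0.1
    efficiency: float = 2.0
    intercept: float = 24.0
    log2_profile: tuple[float, ...] | None = None

    @property
    def slope(self) -> float:
        return -1.0 / math.log10(self.efficiency)


@dataclass(frozen=True)
class CqSimSpec:
    """qPCR simulation: triplicate Cq tables plus dilution series."""

    genes: tuple[CqGeneSpec, ...]
    samples: tuple[str, ...] = field(default_factory=default_cq_samples)
    sample_effect_sd: float = 0.8
    replicate_sd: float = 0.1
    n_replicates: int = 3
    outlier_probability: float = 0.0
    outlier_shift: float = 1.2
    dilution_points: int = 4
    dilution_fold: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.outlier_probability <= 1:
            raise ValueError("outlier_probability must be in [0, 1]")
        if self.dilution_fold <= 1:
            raise ValueError("dilution_fold must be > 1")
        if self.outlier_shift <= 0:
            raise ValueError("outlier_shift must be positive")
        if self.dilution_points < 3:
            raise ValueError("need at least 3 dilution points")
        for g in self.genes:
            if g.log2_profile is not None and len(g.log2_profile) != len(self.samples):
                raise ValueError(
                    f"log2_profile length mismatch for gene {g.gene_id!r}"
                )


@dataclass
class CqDataset:
    """Simulated raw qPCR output: long Cq table + dilution-series table."""

    cq_long: pd.DataFrame  # sample_id, gene_id, replicate, cq
    dilutions: pd.DataFrame  # gene_id, relative_input, replicate, cq

    def mean_cq_matrix(self, outlier_delta: float = 0.5) -> pd.DataFrame:
        """Collapse triplicates and pivot to a genes x samples mean-Cq matrix."""
        collapsed = collapse_table(self.cq_long, outlier_delta)
        mat = collapsed.pivot(index="gene_id", columns="sample_id", values="mean_cq")
        genes = list(dict.fromkeys(self.cq_long["gene_id"]))
        samples = list(dict.fromkeys(self.cq_long["sample_id"]))
        return mat.loc[genes, samples]


def simulate_cq(spec: CqSimSpec) -> tuple[CqDataset, GroundTruth]:
    """Draw a triplicate Cq experiment plus dilution series from a spec.

    Cq_gsr = intercept_g + slope_g * log10(q_gs) + sample_effect_s +
    gene_noise_gs + replicate_noise_gsr, where q_gs = 2^(log2_profile) is
    the gene's true relative template amount. Sample effects are shared by
    all genes in a sample (input-amount variation). Outliers shift one
    replicate of a reaction by +/- outlier_shift with the stated
    probability. Dilution series come from the same curves with replicate
    noise only.
    """
    rng = np.random.default_rng(spec.seed)
    n_s = len(spec.samples)
    sample_effects = rng.normal(0.0, spec.sample_effect_sd, size=n_s)
    rows = []
    for g in spec.genes:
        profile = np.zeros(n_s) if g.log2_profile is None else np.asarray(g.log2_profile)
        q = 2.0 ** profile
        base = g.intercept + g.slope * np.log10(q) + sample_effects
        gene_noise = rng.normal(0.0, g.noise_sd, size=n_s)
        for s_idx, sample in enumerate(spec.samples):
            reps = base[s_idx] + gene_noise[s_idx] + rng.normal(
                0.0, spec.replicate_sd, size=spec.n_replicates
            )
            if spec.outlier_probability > 0 and rng.random() < spec.outlier_probability:
                which = rng.integers(spec.n_replicates)
                reps[which] += spec.outlier_shift * rng.choice([-1.0, 1.0])
            for r_idx, cq in enumerate(reps, start=1):
                rows.append(
                    {
                        "sample_id": sample,
                        "gene_id": g.gene_id,
                        "replicate": r_idx,
                        "cq": float(cq),
                    }
                )
    dil_rows = []
    for g in spec.genes:
        for p in range(spec.dilution_points):
            x = spec.dilution_fold ** (-p)
            true_cq = g.intercept + g.slope * math.log10(x)
            for r_idx in range(1, spec.n_replicates + 1):
                dil_rows.append(
                    {
                        "gene_id": g.gene_id,
                        "relative_input": x,
                        "replicate": r_idx,
                        "cq": float(true_cq + rng.normal(0.0, spec.replicate_sd)),
                    }
                )
    truth = GroundTruth(
        genes=pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in spec.genes],
                "noise_sd": [g.noise_sd for g in spec.genes],
                "efficiency": [g.efficiency for g in spec.genes],
                "slope": [g.slope for g in spec.genes],
                "intercept": [g.intercept for g in spec.genes],
            }
        ).set_index("gene_id"),
        sample_effects=pd.Series(sample_effects, index=list(spec.samples)),
    )
    return (
        CqDataset(pd.DataFrame(rows), pd.DataFrame(dil_rows)),
        truth,
    )


def default_fixture_cq_spec(seed: int = 42) -> CqSimSpec:
    """Fixture qPCR design: 9 stable candidates, one unstable UBQ-like
    reference and 4 targets with planted endocarp/developmental profiles."""
    rng = np.random.default_rng(seed)
    genes: list[CqGeneSpec] = []
    for i in range(1, 10):
        genes.append(
            CqGeneSpec(
                gene_id=f"P{i}",
                noise_sd=float(rng.uniform(0.08, 0.25)),
                intercept=float(rng.uniform(21.0, 27.0)),
            )
        )
    genes.append(CqGeneSpec("UBQ", noise_sd=1.0, intercept=20.0))
    n_s = len(default_cq_samples())
    for j in range(1, 5):
        profile = rng.uniform(-2.0, 2.0, size=n_s)
        genes.append(
            CqGeneSpec(
                gene_id=f"PT{j}",
                noise_sd=0.1,
                intercept=float(rng.uniform(24.0, 30.0)),
                log2_profile=tuple(float(v) for v in profile),
            )
        )
    return CqSimSpec(genes=tuple(genes), outlier_probability=0.03, seed=seed)


def make_fixture_suite(out_dir: str | Path, seed: int = 42) -> dict[str, Path]:
    """Write the canonical small fixture set used by tests and examples.

    Produces a 20-library count matrix with metadata and truth, a qPCR
    experiment (14 assays x 11 samples: 9 candidates, 1 UBQ-like, 4
    targets) with dilution series, the collapsed 10-gene ranking Cq matrix,
    and a normalization schemes file. Deterministic given the seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    count_spec = CountSimSpec(n_genes=200, seed=seed)
    matrix, count_truth = simulate_counts(count_spec)
    paths["counts"] = out / "counts.tsv"
    write_matrix(matrix, paths["counts"])
    meta = pd.DataFrame([vars(m) for m in matrix.libraries])
    paths["meta"] = out / "library_meta.tsv"
    meta.to_csv(paths["meta"], sep="\t", index=False)
    paths["count_truth"] = out / "count_truth.tsv"
    count_truth.genes.to_csv(paths["count_truth"], sep="\t")

    cq_spec = default_fixture_cq_spec(seed)
    dataset, cq_truth = simulate_cq(cq_spec)
    paths["cq_long"] = out / "cq_long.csv"
    dataset.cq_long.to_csv(paths["cq_long"], index=False)
    paths["dilutions"] = out / "dilutions.csv"
    dataset.dilutions.to_csv(paths["dilutions"], index=False)
    paths["cq_truth"] = out / "cq_truth.tsv"
    cq_truth.genes.to_csv(paths["cq_truth"], sep="\t")

    ranking_genes = [f"P{i}" for i in range(1, 10)] + ["UBQ"]
    cq_matrix = dataset.mean_cq_matrix().loc[ranking_genes]
    paths["cq_matrix"] = out / "cq_matrix.tsv"
    cq_matrix.to_csv(paths["cq_matrix"], sep="\t", index_label="gene_id")

    paths["schemes"] = out / "schemes.cfg"
    paths["schemes"].write_text(
        "none:\n"
        "UBQ: UBQ\n"
        "all_four: P2,P3,P7,UBQ\n"
        "three_candidates: P2,P3,P7\n"
        "no_high: P3,P7,UBQ\n"
    )
    return paths
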