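"""Synthetic genotype-phenotype data.

Genotypes are biallelic SNPs drawn at independent loci under Hardy-Weinberg
proportions with per-marker allele frequencies sampled uniformly from a MAF
window. Quantitative traits are built from a sparse set of QTL with i.i.d.
standard-normal effects acting on centred allele counts, either additively,
through pairwise products (epistasis), or both, plus Gaussian environmental
noise calibrated so the realized heritability matches the target exactly.

No linkage disequilibrium is simulated by default: independent loci keep
every downstream oracle exact. An optional block-correlated mode
(``ld_block_size > 1``) copies a latent gamete within blocks with high
probability, giving crude within-block correlation for tests that need it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .genotypes import RawGenotypeTable

__all__ = ["SimConfig", "SimulatedDataset", "simulate_genotypes", "simulate_phenotype", "simulate_dataset"]

ARCHITECTURES = ("additive", "epistatic_pairs", "mixed")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic dataset; every output is a pure function
    of these fields (including ``seed``)."""

    n_individuals: int
    n_markers: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl: int = 20
    h2: float = 0.5
    architecture: str = "additive"
    missing_rate: float = 0.0
    seed: int = 0
    ld_block_size: int = 1  # 1 = independent loci

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValidationError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if self.n_individuals < 2 or self.n_markers < 1:
            raise ValidationError("need n_individuals >= 2 and n_markers >= 1")
        if not (0.0 <= self.h2 <= 1.0):
            raise ValidationError(f"h2 must lie in [0,1], got {self.h2}")
        if self.n_qtl > self.n_markers:
            raise ValidationError("n_qtl cannot exceed n_markers")
        if self.h2 > 0 and self.n_qtl < 1:
            raise ValidationError("h2 > 0 requires at least one QTL")
        if self.architecture not in ARCHITECTURES:
            raise ValidationError(f"architecture must be one of {ARCHITECTURES}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValidationError("missing_rate must lie in [0,1)")
        if self.architecture in ("epistatic_pairs", "mixed") and self.h2 > 0 and self.n_qtl < 2:
            raise ValidationError("epistatic architectures need n_qtl >= 2")


@dataclass
class SimulatedDataset:
    """A simulated trait with its true decomposition.

    phenotype = true_genetic_values + noise, elementwise;
    realized_h2 = var(true_genetic_values) / var(phenotype).
    """

    genotypes: RawGenotypeTable
    phenotype: np.ndarray
    true_genetic_values: np.ndarray
    noise: np.ndarray
    qtl_effects: dict  # marker index (or index pair) -> effect
    realized_h2: float
    config: SimConfig = field(repr=False, default=None)  # type: ignore[assignment]


def simulate_genotypes(config: SimConfig) -> RawGenotypeTable:
    """Draw an n x m allele-count table under HWE with uniform MAF."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n, m = config.n_individuals, config.n_markers
    lo, hi = config.maf_range
    q = rng.uniform(lo, hi, size=m)
    if config.ld_block_size > 1:
        counts = _block_correlated_counts(rng, n, m, q, config.ld_block_size)
    else:
        counts = rng.binomial(2, q, size=(n, m)).astype(float)
    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        counts[mask] = np.nan
    width = max(4, len(str(n)))
    sample_ids = [f"ind{i + 1:0{width}d}" for i in range(n)]
    marker_ids = [f"snp{j + 1:0{max(4, len(str(m)))}d}" for j in range(m)]
    return RawGenotypeTable(sample_ids=sample_ids, marker_ids=marker_ids, counts=counts)


def _block_correlated_counts(
    rng: np.random.Generator, n: int, m: int, q: np.ndarray, block: int
) -> np.ndarray:
    # two latent gametes per block; each locus copies the block gamete with
    # probability 0.9, otherwise segregates independently
    counts = np.zeros((n, m))
    for start in range(0, m, block):
        stop = min(start + block, m)
        width = stop - start
        for g in range(2):  # two haplotypes
            anchor = rng.random((n, 1)) < q[start:stop].mean()
            free = rng.random((n, width)) < q[start:stop]
            copy = rng.random((n, width)) < 0.9
            counts[:, start:stop] += np.where(copy, anchor, free)
    return counts


def _centered_imputed(counts: np.ndarray) -> np.ndarray:
    Z = counts.copy()
    col_mean = np.nanmean(Z, axis=0)
    r, c = np.nonzero(np.isnan(Z))
    Z[r, c] = col_mean[c]
    return Z - Z.mean(axis=0)


def _genetic_values(
    rng: np.random.Generator, Z: np.ndarray, config: SimConfig
) -> tuple[np.ndarray, dict]:
    m = Z.shape[1]
    loci = rng.choice(m, size=config.n_qtl, replace=False)
    effects: dict = {}
    g = np.zeros(Z.shape[0])
    if config.architecture == "additive":
        add, pairs = loci, []
    elif config.architecture == "epistatic_pairs":
        add, pairs = [], _pair_up(loci)
    else:  # mixed: half the loci act additively, the rest in pairs
        half = len(loci) // 2
        add, pairs = loci[:half], _pair_up(loci[half:])
    for j in add:
        beta = rng.standard_normal()
        effects[int(j)] = beta
        g = g + beta * Z[:, j]
    for (j, k) in pairs:
        beta = rng.standard_normal()
        effects[(int(j), int(k))] = beta
        g = g + beta * Z[:, j] * Z[:, k]
    return g, effects


def _pair_up(loci) -> list[tuple[int, int]]:
    loci = list(loci)
    return [(loci[i], loci[i + 1]) for i in range(0, len(loci) - 1, 2)]


def simulate_phenotype(genotypes: RawGenotypeTable, config: SimConfig) -> SimulatedDataset:
    """Attach a quantitative trait to a genotype table.

    Noise is drawn Gaussian, residualized in-sample against the genetic
    values and rescaled so that var(phenotype) = var(genetic) + var(noise)
    holds exactly and realized_h2 equals the target h2 (up to floating
    error). At h2 = 0 the genetic component is identically zero and the
    phenotype is pure unit-variance noise; at h2 = 1 the noise is zero.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = genotypes.n
    if config.h2 == 0.0:
        g = np.zeros(n)
        effects: dict = {}
        e = rng.standard_normal(n)
        e = (e - e.mean()) / e.std()
    else:
        Z = _centered_imputed(genotypes.counts)
        g, effects = _genetic_values(rng, Z, config)
        var_g = float(g.var())
        if var_g == 0.0:
            raise ValidationError(
                "simulated genetic values are constant; increase n or widen maf_range"
            )
        if config.h2 == 1.0:
            e = np.zeros(n)
        else:
            raw = rng.standard_normal(n)
            gc = g - g.mean()
            raw = raw - raw.mean()
            raw = raw - (raw @ gc) / (gc @ gc) * gc  # kill sample covariance
            target_var_e = var_g * (1.0 - config.h2) / config.h2
            e = raw * np.sqrt(target_var_e / raw.var())
    y = g + e
    var_y = float(y.var())
    realized = float(g.var() / var_y) if var_y > 0 else 0.0
    return SimulatedDataset(
        genotypes=genotypes,
        phenotype=y,
        true_genetic_values=g,
        noise=e,
        qtl_effects=effects,
        realized_h2=realized,
        config=config,
    )


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Convenience: genotypes and phenotype in one call."""
    return simulate_phenotype(simulate_genotypes(config), config)
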