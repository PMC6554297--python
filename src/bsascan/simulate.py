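"""Simulation of F2 bulked-segregant sequencing experiments.

The model chain is the one a BSA-seq analysis assumes:

1. two fully inbred parents differing at every mapped SNP; the F1 is
   heterozygous everywhere;
2. F2 individuals are sums of two independent F1 gametes; meiosis follows
   the Haldane model (Poisson crossovers, no interference), so the
   recombination fraction over ``m`` Morgans is ``(1 - exp(-2m)) / 2``;
3. a quantitative trait with per-QTL genotype values ``{-a, d, +a}`` for
   donor dosage ``{0, 1, 2}`` plus Gaussian noise calibrated to a target
   broad-sense heritability of the simulated QTLs;
4. extreme-tail bulks of fixed size, pooled with exactly equal DNA per
   plant;
5. short-read sampling: per SNP and bulk, a read depth from the depth model
   and a binomial draw of donor-allele reads at the bulk allele frequency,
   optionally perturbed by a symmetric per-read error rate.

All randomness descends from one root seed; meiosis, trait noise and read
sampling use independent substreams so stages can be re-run independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeMap, build_genome_map

COUNT_COLUMNS = [
    "chrom",
    "pos",
    "donor_count_high",
    "depth_high",
    "donor_count_low",
    "depth_low",
]


@dataclass(frozen=True)
class QTLSpec:
    """One quantitative trait locus on the map.

    ``additive_effect`` (a) is the trait change per donor-allele
    substitution: homozygote values are -a and +a. ``dominance`` (d) is the
    heterozygote value.
    """

    chrom: str
    pos: int
    additive_effect: float
    dominance: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.additive_effect):
            raise ValueError("additive_effect must be finite")


@dataclass(frozen=True)
class DepthModel:
    """Per-SNP, per-bulk read-depth model: 'fixed' or 'poisson' with a mean."""

    distribution: str = "poisson"
    mean: float = 22.0

    def __post_init__(self) -> None:
        if self.distribution not in ("fixed", "poisson"):
            raise ValueError(f"unknown depth distribution {self.distribution!r}")
        if self.mean < 1:
            raise ValueError("mean depth must be >= 1")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.distribution == "fixed":
            return np.full(n, int(round(self.mean)), dtype=np.int64)
        return rng.poisson(self.mean, size=n).astype(np.int64)


@dataclass(frozen=True)
class F2SimConfig:
    """Full recipe for one simulated bulked-segregant experiment."""

    map: GenomeMap
    qtls: tuple[QTLSpec, ...] = ()
    n_individuals: int = 178
    heritability: float = 0.5
    bulk_size: int = 20
    depth_model: DepthModel = field(default_factory=DepthModel)
    sequencing_error: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.heritability < 1:
            raise ValueError("heritability must be in [0, 1)")
        if 2 * self.bulk_size > self.n_individuals:
            raise ValueError("2 * bulk_size must not exceed n_individuals")
        if not 0 <= self.sequencing_error <= 0.01:
            raise ValueError("sequencing_error must be in [0, 0.01]")


@dataclass(frozen=True)
class SimResult:
    """Everything one simulated experiment produced."""

    config: F2SimConfig
    genotypes: np.ndarray
    phenotypes: np.ndarray
    low_bulk: np.ndarray
    high_bulk: np.ndarray
    counts: pd.DataFrame


def _substreams(seed: int) -> tuple[np.random.Generator, ...]:
    """Independent generators for meiosis, trait noise and read sampling."""
    children = np.random.SeedSequence(seed).spawn(3)
    return tuple(np.random.Generator(np.random.PCG64(c)) for c in children)


def simulate_f2(
    genome_map: GenomeMap,
    n: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate donor-allele dosages for ``n`` F2 individuals.

    Returns an ``(n, n_snps)`` int8 matrix with entries in {0, 1, 2}; SNP
    columns follow the map's chromosome order. Each individual is the sum of
    two independent gametes. Along a chromosome, a gamete's parental phase
    at the leftmost SNP is fair, and the number of crossovers in each
    inter-SNP interval is Poisson with mean equal to the interval's genetic
    length in Morgans (Haldane model, no interference).
    """
    if n < 2:
        raise ValueError("need at least 2 individuals")
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    blocks = []
    for chrom, _ in genome_map.chromosomes:
        morgans = genome_map.genetic_positions(chrom)
        gaps = np.diff(morgans)
        phase0 = rng.integers(0, 2, size=(2 * n, 1))
        if len(gaps):
            crossings = rng.poisson(gaps, size=(2 * n, len(gaps)))
            cum = np.concatenate(
                [np.zeros((2 * n, 1), dtype=np.int64), np.cumsum(crossings, axis=1)],
                axis=1,
            )
        else:
            cum = np.zeros((2 * n, 1), dtype=np.int64)
        haplotypes = (phase0 + cum) % 2
        blocks.append((haplotypes[:n] + haplotypes[n:]).astype(np.int8))
    return np.concatenate(blocks, axis=1)


def simulate_phenotypes(
    genotypes: np.ndarray,
    genome_map: GenomeMap,
    qtls: tuple[QTLSpec, ...] | list[QTLSpec],
    heritability: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Trait values = sum of per-QTL genotype effects + Gaussian noise.

    The noise variance is chosen from the *realized* genetic variance so
    that Var(genetic) / Var(total expected) equals ``heritability``.
    ``heritability = 0`` yields pure unit-variance noise.
    """
    if not 0 <= heritability < 1:
        raise ValueError("heritability must be in [0, 1)")
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    n = genotypes.shape[0]
    genetic = np.zeros(n)
    for qtl in qtls:
        col = genome_map.snp_column_index(qtl.chrom, qtl.pos)  # raises if off-map
        dosage = genotypes[:, col]
        genetic += np.choose(
            dosage, [-qtl.additive_effect, qtl.dominance, qtl.additive_effect]
        )
    var_g = float(np.var(genetic))
    if heritability == 0 or not qtls:
        # zero heritability: the genetic values contribute nothing
        return rng.normal(0.0, 1.0, size=n)
    if var_g == 0:
        raise ValueError("no realized genetic variance; cannot calibrate heritability")
    var_e = var_g * (1 - heritability) / heritability
    return genetic + rng.normal(0.0, np.sqrt(var_e), size=n)


def select_bulks(
    phenotypes: np.ndarray, bulk_size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the low and high phenotypic tails.

    Ties break deterministically by ascending individual index, so the two
    bulks are always disjoint. Returns ``(low, high)``, each sorted.
    """
    phenotypes = np.asarray(phenotypes)
    n = len(phenotypes)
    if bulk_size < 1:
        raise ValueError("bulk_size must be >= 1")
    if 2 * bulk_size > n:
        raise ValueError("2 * bulk_size exceeds population size")
    order = np.argsort(phenotypes, kind="stable")
    low = np.sort(order[:bulk_size])
    high = np.sort(order[-bulk_size:])
    return low, high


def simulate_bulk_reads(
    genotypes: np.ndarray,
    genome_map: GenomeMap,
    high_bulk: np.ndarray,
    low_bulk: np.ndarray,
    depth_model: DepthModel = DepthModel(),
    sequencing_error: float = 0.001,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Pooled short-read counts per SNP for the two bulks.

    For each SNP the bulk donor-allele frequency is ``p = mean(dosage)/2``
    over the bulk's members (equal DNA per plant). The read depth is drawn
    per SNP and bulk from ``depth_model``; donor read counts are binomial at
    the error-perturbed frequency ``p' = p(1-e) + (1-p)e``. Zero-depth draws
    are retained (the SNP index is undefined there and is flagged
    downstream, not silently dropped).
    """
    if len(high_bulk) == 0 or len(low_bulk) == 0:
        raise ValueError("bulks must be non-empty")
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    table = genome_map.snp_table()
    e = sequencing_error
    out = {}
    for label, bulk in (("high", high_bulk), ("low", low_bulk)):
        p = genotypes[bulk].mean(axis=0) / 2.0
        p_eff = p * (1 - e) + (1 - p) * e
        depth = depth_model.draw(len(p), rng)
        out[f"donor_count_{label}"] = rng.binomial(depth, p_eff)
        out[f"depth_{label}"] = depth
    return pd.DataFrame({"chrom": table["chrom"], "pos": table["pos"], **out})[
        COUNT_COLUMNS
    ]


def simulate_experiment(config: F2SimConfig) -> SimResult:
    """Run the full chain: meiosis -> trait -> bulks -> pooled reads."""
    rng_meiosis, rng_noise, rng_reads = _substreams(config.seed)
    genotypes = simulate_f2(config.map, config.n_individuals, rng=rng_meiosis)
    phenotypes = simulate_phenotypes(
        genotypes, config.map, config.qtls, config.heritability, rng=rng_noise
    )
    low, high = select_bulks(phenotypes, config.bulk_size)
    counts = simulate_bulk_reads(
        genotypes,
        config.map,
        high,
        low,
        depth_model=config.depth_model,
        sequencing_error=config.sequencing_error,
        rng=rng_reads,
    )
    return SimResult(config, genotypes, phenotypes, low, high, counts)


def config_from_dict(doc: dict) -> F2SimConfig:
    """Build an :class:`F2SimConfig` from a flat YAML/JSON-style document."""
    doc = dict(doc)
    lengths = doc.pop("chrom_lengths", None)
    if lengths == "rice12":
        lengths = None
    genome_map = build_genome_map(
        chrom_lengths=lengths,
        snp_spacing=doc.pop("snp_spacing", None),
        snps_per_chrom=doc.pop("snps_per_chrom", None),
        cm_per_mb=doc.pop("cm_per_mb", 4.0),
    )
    qtls = tuple(QTLSpec(**q) for q in doc.pop("qtls", []))
    depth = doc.pop("depth", None)
    depth_model = DepthModel(**depth) if depth else DepthModel()
    return F2SimConfig(map=genome_map, qtls=qtls, depth_model=depth_model, **doc)
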