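"""Genome maps for F2 bulked-segregant simulation.

A :class:`GenomeMap` is the minimal description the simulator needs: an
ordered set of chromosomes with physical lengths, the physical positions of
the biallelic SNPs segregating between the two inbred parents, and a single
uniform recombination rate (centimorgan per megabase) used to convert
physical to genetic distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Physical lengths (bp) of the 12 rice chromosomes, used as the default
#: genome for simulations at rice scale.
RICE_CHROM_LENGTHS: dict[str, int] = {
    "chr01": 43_270_923,
    "chr02": 35_937_250,
    "chr03": 36_413_819,
    "chr04": 35_502_694,
    "chr05": 29_958_434,
    "chr06": 31_248_787,
    "chr07": 29_697_621,
    "chr08": 28_443_022,
    "chr09": 23_012_720,
    "chr10": 23_207_287,
    "chr11": 29_021_106,
    "chr12": 27_531_856,
}


@dataclass(frozen=True)
class GenomeMap:
    """Chromosome lengths, SNP positions and a uniform recombination rate.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    snp_positions
        Mapping chromosome name -> sorted 1-based SNP positions (bp).
    cm_per_mb
        Recombination rate in centimorgan per megabase (> 0).
    """

    chromosomes: tuple[tuple[str, int], ...]
    snp_positions: dict[str, np.ndarray] = field(repr=False)
    cm_per_mb: float = 4.0

    def __post_init__(self) -> None:
        if self.cm_per_mb <= 0:
            raise ValueError(f"cm_per_mb must be > 0, got {self.cm_per_mb}")
        lengths = dict(self.chromosomes)
        if set(self.snp_positions) - set(lengths):
            raise ValueError("snp_positions refers to unknown chromosomes")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            pos = np.asarray(self.snp_positions[name], dtype=np.int64)
            if pos.ndim != 1 or len(pos) == 0:
                raise ValueError(f"chromosome {name!r} has no SNPs")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"SNP positions on {name!r} must be strictly increasing")
            if pos[0] < 1 or pos[-1] > length:
                raise ValueError(f"SNP positions on {name!r} fall outside [1, {length}]")
            object.__setattr__(self, "snp_positions", {**self.snp_positions, name: pos})

    @property
    def chrom_names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def n_snps(self) -> int:
        return int(sum(len(p) for p in self.snp_positions.values()))

    def snp_table(self) -> pd.DataFrame:
        """All SNPs as a DataFrame with columns ``chrom`` and ``pos``."""
        frames = [
            pd.DataFrame({"chrom": name, "pos": self.snp_positions[name]})
            for name, _ in self.chromosomes
        ]
        return pd.concat(frames, ignore_index=True)

    def genetic_positions(self, chrom: str) -> np.ndarray:
        """SNP positions on *chrom* in Morgans from the chromosome start."""
        return self.snp_positions[chrom] * (self.cm_per_mb / 1e8)

    def snp_column_index(self, chrom: str, pos: int) -> int:
        """Column index of SNP (chrom, pos) in the concatenated genotype matrix."""
        offset = 0
        for name, _ in self.chromosomes:
            positions = self.snp_positions[name]
            if name == chrom:
                hit = np.searchsorted(positions, pos)
                if hit >= len(positions) or positions[hit] != pos:
                    raise ValueError(f"position {chrom}:{pos} is not a mapped SNP")
                return offset + int(hit)
            offset += len(positions)
        raise ValueError(f"unknown chromosome {chrom!r}")


def build_genome_map(
    chrom_lengths: dict[str, int] | list[int] | None = None,
    snp_spacing: int | None = None,
    snps_per_chrom: int | None = None,
    cm_per_mb: float = 4.0,
) -> GenomeMap:
    """Lay out evenly spaced SNPs on each chromosome.

    Exactly one of ``snp_spacing`` (a fixed bp spacing; SNPs sit at
    ``spacing, 2*spacing, ...`` up to the chromosome end) or
    ``snps_per_chrom`` (a fixed count, spread evenly) must be given.
    ``chrom_lengths`` defaults to the 12 rice chromosomes.
    """
    if chrom_lengths is None:
        chrom_lengths = RICE_CHROM_LENGTHS
    if isinstance(chrom_lengths, dict):
        items = list(chrom_lengths.items())
    else:
        items = [(f"chr{i + 1:02d}", int(l)) for i, l in enumerate(chrom_lengths)]
    if (snp_spacing is None) == (snps_per_chrom is None):
        raise ValueError("give exactly one of snp_spacing or snps_per_chrom")

    positions: dict[str, np.ndarray] = {}
    for name, length in items:
        if length <= 0:
            raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        if snp_spacing is not None:
            if snp_spacing <= 0:
                raise ValueError(f"snp_spacing must be positive, got {snp_spacing}")
            pos = np.arange(snp_spacing, length + 1, snp_spacing, dtype=np.int64)
        else:
            if snps_per_chrom < 2:
                raise ValueError("snps_per_chrom must be >= 2")
            pos = np.unique(
                np.round(np.linspace(1, length, snps_per_chrom)).astype(np.int64)
            )
        if len(pos) < 2:
            raise ValueError(
                f"spacing {snp_spacing} yields fewer than 2 SNPs on {name!r} "
                f"(length {length})"
            )
        positions[name] = pos
    return GenomeMap(tuple(items), positions, cm_per_mb)
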