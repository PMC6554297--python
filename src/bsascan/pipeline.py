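"""End-to-end driver: counts -> indices -> null bands -> windows -> regions."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .snp_index import compute_snp_index, filter_by_depth, filter_low_index_both
from .windows import DeltaNull, call_regions, ci_table, sliding_windows

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Stage parameters for the scan pipeline; defaults follow the standard
    QTL-seq settings (2-Mb windows, 10-kb step, depth >= 29 in both bulks,
    index < 0.3 both-bulk removal, bulks of 20, 100k null replicates)."""

    window_bp: int = 2_000_000
    step_bp: int = 10_000
    min_depth: int = 29
    low_index_threshold: float = 0.3
    min_snps: int = 3
    bulk_size: int = 20
    n_sims: int = 100_000
    level: float = 0.95
    levels: tuple[float, ...] = (0.95, 0.99)
    p_threshold: float = 0.05
    max_gap_windows: int = 2
    seed: int = 0
    donor_pos: str = "donor"
    donor_neg: str = "other"
    chrom_lengths: dict | None = None

    def __post_init__(self) -> None:
        if self.window_bp < self.step_bp:
            raise ValueError("window_bp must be >= step_bp")
        if not 0 < self.low_index_threshold < 1:
            raise ValueError("low_index_threshold must be in (0, 1)")
        if self.min_depth < 1 or self.bulk_size < 1 or self.n_sims < 1000:
            raise ValueError("min_depth, bulk_size and n_sims out of range")
        if not 0 < self.level < 1 or not 0 < self.p_threshold < 1:
            raise ValueError("level and p_threshold must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "levels" in doc:
            doc["levels"] = tuple(doc["levels"])
        return cls(**doc)

    def meta(self) -> dict:
        doc = asdict(self)
        doc.pop("chrom_lengths")
        return doc


def attach_p_values(index_df: pd.DataFrame, null: DeltaNull) -> pd.DataFrame:
    """Add per-SNP mean depth and two-sided empirical p-value columns."""
    out = index_df.copy()
    out["depth_mean"] = (out["depth_high"] + out["depth_low"]) / 2.0
    out["p"] = null.empirical_p(out["delta"].to_numpy(), out["depth_mean"].to_numpy())
    return out


def run_pipeline(
    counts: pd.DataFrame,
    config: RunConfig,
    out_prefix=None,
    null: DeltaNull | None = None,
) -> dict:
    """Run index -> ci -> scan on a counts table; optionally write artifacts.

    Returns a dict with the index table, window table, CI table and region
    table. A prebuilt ``null`` model (matching the config's bulk size,
    n_sims and seed) may be passed to share the cached null samples across
    runs. With ``out_prefix`` set, writes <prefix>.index.tsv,
    <prefix>.windows.tsv, <prefix>.ci.tsv, <prefix>.regions.tsv and
    <prefix>.regions.bed, each headed by the run parameters and seed;
    identical counts + config give byte-identical artifacts.
    """
    logger.info("input: %d SNPs", len(counts))
    idx = compute_snp_index(counts)
    idx = filter_by_depth(idx, config.min_depth)
    idx = filter_low_index_both(idx, config.low_index_threshold)
    if null is None:
        null = DeltaNull(
            bulk_size=config.bulk_size, n_sims=config.n_sims, seed=config.seed
        )
    elif (null.bulk_size, null.n_sims, null.seed) != (
        config.bulk_size, config.n_sims, config.seed
    ):
        raise ValueError("supplied null model does not match the run config")
    idx = attach_p_values(idx, null)
    windows = sliding_windows(
        idx,
        window_bp=config.window_bp,
        step_bp=config.step_bp,
        min_snps=config.min_snps,
        chrom_lengths=config.chrom_lengths,
    )
    depths = np.unique(
        np.rint(windows["mean_depth"].dropna()).astype(int)
    )
    depths = depths[depths >= 1]
    ci = ci_table(depths if len(depths) else [config.min_depth],
                  levels=config.levels, null=null)
    regions = call_regions(
        windows,
        null,
        level=config.level,
        p_threshold=config.p_threshold,
        max_gap_windows=config.max_gap_windows,
        donor_pos=config.donor_pos,
        donor_neg=config.donor_neg,
    )
    logger.info("called %d candidate region(s)", len(regions))
    if out_prefix is not None:
        prefix = str(out_prefix)
        meta = config.meta()
        io.write_table(idx, f"{prefix}.index.tsv", meta)
        io.write_table(windows, f"{prefix}.windows.tsv", meta)
        io.write_table(ci, f"{prefix}.ci.tsv", meta)
        io.write_regions_table(regions, f"{prefix}.regions.tsv", ci=ci, meta=meta)
        io.write_regions_bed(regions, f"{prefix}.regions.bed", meta)
    return {"index": idx, "windows": windows, "ci": ci, "regions": regions}
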