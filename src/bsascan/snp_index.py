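"""Per-bulk SNP index, depth/low-index filtering, and Δ(SNP index).

The SNP index of a bulk at a SNP is the fraction of its reads carrying the
donor allele (the allele from the non-reference parent; 1.0 means the bulk
is pure donor there). Δ(SNP index) is the high bulk's index minus the low
bulk's; it is 0 in expectation at unlinked SNPs and departs from 0 near a
locus that the bulk selection enriched.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .simulate import COUNT_COLUMNS

logger = logging.getLogger(__name__)

INDEX_COLUMNS = COUNT_COLUMNS + ["index_high", "index_low", "delta"]


def _require_columns(df: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")


def compute_snp_index(counts: pd.DataFrame, drop_undefined: bool = True) -> pd.DataFrame:
    """Add ``index_high``, ``index_low`` and ``delta`` columns.

    index = donor reads / depth per bulk; delta = index_high - index_low.
    Records with zero depth in either bulk have an undefined index; they are
    dropped (and counted in the log) when ``drop_undefined`` is true,
    otherwise kept with NaN indices.
    """
    _require_columns(counts, COUNT_COLUMNS)
    for side in ("high", "low"):
        donor = counts[f"donor_count_{side}"]
        depth = counts[f"depth_{side}"]
        if ((donor < 0) | (donor > depth)).any():
            raise ValueError(f"donor counts outside [0, depth] in {side} bulk")
    out = counts.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        out["index_high"] = np.where(
            out["depth_high"] > 0, out["donor_count_high"] / out["depth_high"], np.nan
        )
        out["index_low"] = np.where(
            out["depth_low"] > 0, out["donor_count_low"] / out["depth_low"], np.nan
        )
    out["delta"] = out["index_high"] - out["index_low"]
    undefined = out["index_high"].isna() | out["index_low"].isna()
    if drop_undefined and undefined.any():
        logger.info("dropped %d SNPs with zero depth in a bulk", int(undefined.sum()))
        out = out[~undefined].reset_index(drop=True)
    return out


def filter_by_depth(records: pd.DataFrame, min_depth: int) -> pd.DataFrame:
    """Keep SNPs with depth >= ``min_depth`` in BOTH bulks (boundary inclusive)."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    _require_columns(records, ["depth_high", "depth_low"])
    keep = (records["depth_high"] >= min_depth) & (records["depth_low"] >= min_depth)
    logger.info(
        "depth filter (>= %d in both bulks): %d of %d SNPs kept",
        min_depth,
        int(keep.sum()),
        len(records),
    )
    return records[keep].reset_index(drop=True)


def filter_low_index_both(records: pd.DataFrame, threshold: float = 0.3) -> pd.DataFrame:
    """Remove SNPs whose index is strictly below ``threshold`` in BOTH bulks.

    Such SNPs are likely sequencing or alignment artifacts (a real donor
    allele segregating in the cross should reach the threshold in at least
    one extreme bulk). Removal is strict: a record at exactly the threshold
    in either bulk is kept.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    _require_columns(records, ["index_high", "index_low"])
    drop = (records["index_high"] < threshold) & (records["index_low"] < threshold)
    logger.info(
        "low-index filter (< %.3g in both bulks): %d of %d SNPs kept",
        threshold,
        int((~drop).sum()),
        len(records),
    )
    return records[~drop].reset_index(drop=True)
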