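"""Sliding-window genome scan with simulation-based null confidence bands.

The null model for Δ(SNP index) at a given read depth: each bulk is an
independent draw of ``bulk_size`` F2 individuals whose donor-allele dosages
segregate 1:2:1, pooled and sequenced to the given depth with binomial read
sampling. Two-sided empirical quantiles of the simulated null Δ give
per-depth confidence bands; an observed Δ is scored by a two-sided
empirical p-value against the same sample.

Windows are 1-based closed intervals starting at 1, 1+step, ... on each
chromosome; a SNP at position p belongs to window [s, s + window - 1] iff
s <= p <= s + window - 1. Window statistics are unweighted means over the
member SNPs. A window is called significant when |mean Δ| exceeds the
confidence band at the window's (rounded mean) depth AND the mean per-SNP
p-value is below the p threshold; runs of same-sign significant windows
merge into candidate QTL regions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

WINDOW_VALUE_COLUMNS = {
    "index_high": "mean_index_high",
    "index_low": "mean_index_low",
    "delta": "mean_delta",
    "p": "mean_p",
    "depth_mean": "mean_depth",
}


def null_delta_distribution(
    depth: int,
    bulk_size: int = 20,
    n_sims: int = 100_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Monte-Carlo sample of Δ(SNP index) under the no-linkage null.

    Each replicate: for each bulk independently, draw ``bulk_size`` F2
    dosages ~ Binomial(2, 1/2) (the 1:2:1 ratio), take the pooled donor
    frequency p = mean(dosage)/2, draw donor reads ~ Binomial(depth, p);
    Δ = high index - low index.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    dosages = rng.binomial(2, 0.5, size=(2, n_sims, bulk_size))
    p_bulk = dosages.mean(axis=2) / 2.0
    reads = rng.binomial(depth, p_bulk)
    return (reads[0] - reads[1]) / depth


class DeltaNull:
    """Cache of null Δ samples per read depth, with quantile bands and p-values.

    One root seed; the sample for each depth comes from an independent,
    depth-keyed substream, so the table is reproducible regardless of the
    order in which depths are requested.
    """

    def __init__(self, bulk_size: int = 20, n_sims: int = 100_000, seed: int = 0):
        if n_sims < 1000:
            raise ValueError("n_sims too small for stable quantiles")
        self.bulk_size = bulk_size
        self.n_sims = n_sims
        self.seed = seed
        self._samples: dict[int, np.ndarray] = {}
        self._abs_sorted: dict[int, np.ndarray] = {}

    def sample(self, depth: int) -> np.ndarray:
        depth = int(depth)
        if depth < 1:
            raise ValueError("depth must be >= 1")
        if depth not in self._samples:
            rng = np.random.Generator(
                np.random.PCG64(np.random.SeedSequence(entropy=self.seed, spawn_key=(depth,)))
            )
            s = null_delta_distribution(
                depth, bulk_size=self.bulk_size, n_sims=self.n_sims, rng=rng
            )
            self._samples[depth] = s
            self._abs_sorted[depth] = np.sort(np.abs(s))
        return self._samples[depth]

    def bounds(self, depth: int, level: float = 0.95) -> tuple[float, float]:
        """Two-sided (lower, upper) band: the (1-L)/2 and 1-(1-L)/2 quantiles."""
        if not 0 < level < 1:
            raise ValueError("level must be in (0, 1)")
        tail = (1 - level) / 2
        s = self.sample(depth)
        return float(np.quantile(s, tail)), float(np.quantile(s, 1 - tail))

    def empirical_p(self, delta, depth) -> np.ndarray:
        """Two-sided empirical p with +1/(n+1) continuity correction.

        ``depth`` may be a scalar or a per-value array; values are grouped
        by rounded depth so each group is scored against its own null.
        """
        delta = np.atleast_1d(np.asarray(delta, dtype=float))
        depth_arr = np.broadcast_to(
            np.atleast_1d(np.asarray(depth)), delta.shape
        ).astype(float)
        depth_int = np.maximum(np.rint(depth_arr).astype(int), 1)
        p = np.empty_like(delta)
        for d in np.unique(depth_int):
            self.sample(int(d))
            abs_null = self._abs_sorted[int(d)]
            mask = depth_int == d
            n_ge = len(abs_null) - np.searchsorted(abs_null, np.abs(delta[mask]), side="left")
            p[mask] = (n_ge + 1) / (len(abs_null) + 1)
        return p


def ci_table(
    depths,
    levels=(0.95, 0.99),
    bulk_size: int = 20,
    n_sims: int = 100_000,
    seed: int = 0,
    null: DeltaNull | None = None,
) -> pd.DataFrame:
    """Per-depth two-sided null quantile bands as a tidy table.

    Columns: depth, then lower_<level> / upper_<level> per requested level.
    """
    if null is None:
        null = DeltaNull(bulk_size=bulk_size, n_sims=n_sims, seed=seed)
    rows = []
    for depth in sorted(int(d) for d in depths):
        row: dict[str, float] = {"depth": depth}
        for level in levels:
            lo, hi = null.bounds(depth, level)
            key = f"{level:g}".replace("0.", "")
            row[f"lower_{key}"] = lo
            row[f"upper_{key}"] = hi
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs.update(bulk_size=null.bulk_size, n_sims=null.n_sims, seed=null.seed)
    return out


def empirical_p(delta: float, null_sample: np.ndarray) -> float:
    """Two-sided empirical p of one Δ against a null sample."""
    null_sample = np.asarray(null_sample)
    if null_sample.size == 0:
        raise ValueError("null sample is empty")
    n_ge = int(np.sum(np.abs(null_sample) >= abs(delta)))
    return (n_ge + 1) / (len(null_sample) + 1)


def _check_sorted(records: pd.DataFrame) -> None:
    for chrom, grp in records.groupby("chrom", sort=False):
        if np.any(np.diff(grp["pos"].to_numpy()) < 0):
            raise ValueError(f"records not sorted by position on {chrom!r}")


def sliding_windows(
    records: pd.DataFrame,
    window_bp: int = 2_000_000,
    step_bp: int = 10_000,
    min_snps: int = 3,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Windowed means of SNP indices, Δ, p-values and depth.

    Emits one row per window per chromosome with ``n_snps`` and the mean of
    every value column present among index_high / index_low / delta / p /
    depth_mean; means are NaN where ``n_snps < min_snps``. Windows run from
    start 1 in steps of ``step_bp`` while the start lies on the chromosome
    (length taken from ``chrom_lengths`` or the last SNP).
    """
    if window_bp < step_bp:
        raise ValueError("window_bp must be >= step_bp")
    if "chrom" not in records.columns or "pos" not in records.columns:
        raise ValueError("records need chrom and pos columns")
    _check_sorted(records)
    value_cols = [c for c in WINDOW_VALUE_COLUMNS if c in records.columns]
    frames = []
    for chrom in pd.unique(records["chrom"]):
        grp = records[records["chrom"] == chrom]
        pos = grp["pos"].to_numpy()
        length = (chrom_lengths or {}).get(chrom, int(pos[-1]))
        starts = np.arange(1, length + 1, step_bp, dtype=np.int64)
        ends = starts + window_bp - 1
        i0 = np.searchsorted(pos, starts, side="left")
        i1 = np.searchsorted(pos, ends, side="right")
        n_snps = i1 - i0
        values = {c: grp[c].to_numpy() for c in value_cols}
        means: dict[str, np.ndarray] = {
            WINDOW_VALUE_COLUMNS[c]: np.full(len(starts), np.nan) for c in value_cols
        }
        for w in range(len(starts)):
            if n_snps[w] >= min_snps:
                for c in value_cols:
                    means[WINDOW_VALUE_COLUMNS[c]][w] = values[c][i0[w] : i1[w]].mean()
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "window_start": starts,
                    "window_end": ends,
                    "n_snps": n_snps,
                    **means,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


REGION_COLUMNS = [
    "chrom",
    "start",
    "end",
    "interval_mb",
    "n_windows",
    "delta_min",
    "delta_max",
    "level",
    "donor",
]


def region_summary(
    chrom: str,
    start: int,
    end: int,
    deltas,
    level: float,
    n_windows: int = 0,
    donor_pos: str = "donor",
    donor_neg: str = "other",
) -> dict:
    """One called region's summary row; interval length is (end-start)/1e6 Mb."""
    if start >= end:
        raise ValueError("region start must precede end")
    deltas = np.asarray(deltas, dtype=float)
    delta_max = float(deltas.max())
    return {
        "chrom": chrom,
        "start": int(start),
        "end": int(end),
        "interval_mb": (end - start) / 1e6,
        "n_windows": int(n_windows),
        "delta_min": float(deltas.min()),
        "delta_max": delta_max,
        "level": level,
        "donor": donor_pos if delta_max > 0 else donor_neg,
    }


def call_regions(
    windows: pd.DataFrame,
    null: DeltaNull,
    level: float = 0.95,
    p_threshold: float = 0.05,
    max_gap_windows: int = 2,
    donor_pos: str = "donor",
    donor_neg: str = "other",
) -> pd.DataFrame:
    """Merge runs of significant windows into candidate QTL regions.

    A window is significant when |mean Δ| exceeds the two-sided null band
    at the window's rounded mean depth and its mean per-SNP p-value is
    below ``p_threshold``. Same-sign significant windows on a chromosome
    merge across gaps of at most ``max_gap_windows`` non-significant
    windows; a sign change always splits. Region bounds are the outermost
    member windows' bounds. Because successive windows overlap (the step is
    much smaller than the window), runs separated by a few steps can still
    span the same physical interval; same-sign regions whose physical
    extents overlap are therefore merged in a final pass, so the caller
    never reports two overlapping regions for one locus.
    """
    required = {"chrom", "window_start", "window_end", "mean_delta", "mean_p", "mean_depth"}
    missing = required - set(windows.columns)
    if missing:
        raise ValueError(f"windows table missing columns: {sorted(missing)}")
    regions: list[dict] = []
    for chrom in pd.unique(windows["chrom"]):
        grp = windows[windows["chrom"] == chrom].sort_values("window_start")
        delta = grp["mean_delta"].to_numpy()
        p = grp["mean_p"].to_numpy()
        depth = grp["mean_depth"].to_numpy()
        starts = grp["window_start"].to_numpy()
        ends = grp["window_end"].to_numpy()
        defined = ~np.isnan(delta) & ~np.isnan(p) & ~np.isnan(depth)
        depth_int = np.where(defined, np.rint(np.nan_to_num(depth)), 0).astype(int)
        upper = np.full(len(grp), np.inf)
        for d in np.unique(depth_int[defined]):
            if d < 1:
                continue
            _, hi = null.bounds(int(d), level)
            upper[defined & (depth_int == d)] = hi
        sig = defined & (np.abs(delta) > upper) & (p < p_threshold)
        current: list[int] = []
        gap = 0
        sign = 0

        def flush() -> None:
            if current:
                idx = np.array(current)
                regions.append(
                    region_summary(
                        chrom,
                        int(starts[idx].min()),
                        int(ends[idx].max()),
                        delta[idx],
                        level,
                        n_windows=len(idx),
                        donor_pos=donor_pos,
                        donor_neg=donor_neg,
                    )
                )

        for i in range(len(grp)):
            if sig[i]:
                s = 1 if delta[i] > 0 else -1
                if current and s != sign:
                    flush()
                    current = []
                current.append(i)
                sign = s
                gap = 0
            elif current:
                gap += 1
                if gap > max_gap_windows:
                    flush()
                    current = []
                    gap = 0
        flush()
    merged: list[dict] = []
    for row in regions:
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and prev["chrom"] == row["chrom"]
            and prev["donor"] == row["donor"]
            and row["start"] <= prev["end"]
        ):
            prev["end"] = max(prev["end"], row["end"])
            prev["interval_mb"] = (prev["end"] - prev["start"]) / 1e6
            prev["n_windows"] += row["n_windows"]
            prev["delta_min"] = min(prev["delta_min"], row["delta_min"])
            prev["delta_max"] = max(prev["delta_max"], row["delta_max"])
        else:
            merged.append(dict(row))
    return pd.DataFrame(merged, columns=REGION_COLUMNS)
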