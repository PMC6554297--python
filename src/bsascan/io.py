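"""Readers and writers for the formats the pipeline touches.

Counts travel as a six-column TSV (chrom, pos, donor_count_high,
depth_high, donor_count_low, depth_low) or as a minimal VCF 4.2 with two
samples whose AD field carries (reference, donor) read counts. Positions
are 1-based inclusive in TSV/VCF-facing files and 0-based half-open in BED
output, per each format's convention. Every writer prepends '#'-comment
header lines recording the package version, seed and stage parameters so a
run is auditable from its artifacts alone.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .simulate import COUNT_COLUMNS

logger = logging.getLogger(__name__)


def _header_lines(meta: dict | None) -> str:
    lines = [f"# bsascan {__version__}"]
    for key, value in (meta or {}).items():
        lines.append(f"# {key}: {value}")
    return "\n".join(lines) + "\n"


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """TSV with '#'-comment header; floats at full round-trip precision."""
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n", float_format="%.10g")


def read_counts_tsv(path) -> pd.DataFrame:
    """Read a counts TSV, validating types and the count <= depth invariant.

    Tolerates '#' comments, mixed line endings and stray whitespace; rows
    violating 0 <= donor count <= depth are reported by 1-based data-row
    number.
    """
    df = pd.read_csv(path, sep="\t", comment="#", skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[COUNT_COLUMNS].copy()
    df["chrom"] = df["chrom"].astype(str).str.strip()
    for col in COUNT_COLUMNS[1:]:
        df[col] = pd.to_numeric(df[col], errors="raise").astype(np.int64)
    bad_rows = []
    for side in ("high", "low"):
        bad = (df[f"donor_count_{side}"] < 0) | (
            df[f"donor_count_{side}"] > df[f"depth_{side}"]
        )
        bad_rows.extend((df.index[bad] + 1).tolist())
    if bad_rows:
        raise ValueError(
            f"{path}: donor count outside [0, depth] on data row(s) "
            f"{sorted(set(bad_rows))}"
        )
    if (df["pos"] < 1).any():
        raise ValueError(f"{path}: positions must be >= 1")
    return df


def write_counts_tsv(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    write_table(df[COUNT_COLUMNS], path, meta)


def write_counts_vcf(
    df: pd.DataFrame,
    path,
    high_sample: str = "HGE",
    low_sample: str = "LGE",
    contig_lengths: dict[str, int] | None = None,
    meta: dict | None = None,
) -> None:
    """Minimal VCF 4.2 with per-sample AD = (reference, donor) counts.

    Genotypes are written as './.' — pooled bulks have no single genotype —
    and placeholder REF/ALT alleles A/T mark each site as a biallelic SNP.
    """
    path = Path(path)
    lengths = dict(contig_lengths or {})
    for chrom, grp in df.groupby("chrom", sort=False):
        lengths.setdefault(chrom, int(grp["pos"].max()))
    with open(path, "w", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=bsascan {__version__}\n")
        for key, value in (meta or {}).items():
            fh.write(f"##bsascan_{key}={value}\n")
        for chrom in pd.unique(df["chrom"]):
            fh.write(f"##contig=<ID={chrom},length={lengths[chrom]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Read depth per allele (ref,donor)">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{high_sample}\t{low_sample}\n"
        )
        for row in df.itertuples(index=False):
            ad_high = f"{row.depth_high - row.donor_count_high},{row.donor_count_high}"
            ad_low = f"{row.depth_low - row.donor_count_low},{row.donor_count_low}"
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\tA\tT\t.\tPASS\t.\tGT:AD\t"
                f"./.:{ad_high}\t./.:{ad_low}\n"
            )


def read_counts_vcf(
    path, high_sample: str | None = None, low_sample: str | None = None
) -> tuple[pd.DataFrame, int]:
    """Read per-bulk AD counts from a VCF; donor allele = ALT.

    Keeps biallelic SNPs only; multiallelic sites and indels are skipped
    and counted (returned alongside the table and logged). The two bulk
    samples default to the first two samples in the file.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(samples) < 2:
        raise ValueError(f"{path}: need two bulk samples, found {samples}")
    high = high_sample or samples[0]
    low = low_sample or samples[1]
    for name in (high, low):
        if name not in samples:
            raise ValueError(f"{path}: sample {name!r} not in VCF ({samples})")
    hi_idx, lo_idx = samples.index(high), samples.index(low)
    rows = []
    skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1 or len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            skipped += 1
            continue
        ad = variant.format("AD")
        if ad is None:
            raise ValueError(
                f"{path}: missing AD field at {variant.CHROM}:{variant.POS} "
                f"for samples {high!r}/{low!r}"
            )
        ad = np.asarray(ad)
        rows.append(
            (
                variant.CHROM,
                variant.POS,
                int(ad[hi_idx, 1]),
                int(ad[hi_idx].sum()),
                int(ad[lo_idx, 1]),
                int(ad[lo_idx].sum()),
            )
        )
    if skipped:
        logger.info("skipped %d non-biallelic-SNP records in %s", skipped, path)
    df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    return df, skipped


def write_regions_bed(regions: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Regions as BED: 0-based half-open, name=donor, score=1000*|delta_max|."""
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        fh.write(_header_lines(meta))
        for i, row in enumerate(regions.itertuples(index=False), start=1):
            score = min(1000, int(round(1000 * abs(row.delta_max))))
            fh.write(
                f"{row.chrom}\t{row.start - 1}\t{row.end}\t"
                f"region{i}_{row.donor}\t{score}\t.\n"
            )


def write_regions_table(
    regions: pd.DataFrame,
    path,
    ci: pd.DataFrame | None = None,
    meta: dict | None = None,
) -> None:
    """Region summary table (one row per candidate QTL, 1-based bounds).

    When a CI table is given, the bounds at each region's nearest depth row
    are appended so the table is self-contained for reporting.
    """
    out = regions.copy()
    out.insert(0, "qtl", [f"q{i}" for i in range(1, len(out) + 1)])
    if ci is not None and len(ci) and len(out):
        upper_cols = [c for c in ci.columns if c.startswith("upper_")]
        for col in upper_cols:
            out[col] = float(ci[col].iloc[0]) if len(ci) == 1 else np.nan
        if len(ci) > 1 and "mean_depth" in regions.columns:
            depths = ci["depth"].to_numpy()
            for col in upper_cols:
                nearest = np.abs(
                    depths[None, :] - regions["mean_depth"].to_numpy()[:, None]
                ).argmin(axis=1)
                out[col] = ci[col].to_numpy()[nearest]
    write_table(out, path, meta)


def read_marker_tables(genotypes_path, phenotypes_path):
    """Genotype TSV (rows=individuals, columns=markers, codes A/H/B or 0/1/2)
    and phenotype TSV; joined on an 'id' column when both have one, else by
    row order."""
    geno = pd.read_csv(genotypes_path, sep="\t", comment="#")
    phen = pd.read_csv(phenotypes_path, sep="\t", comment="#")
    if "id" in geno.columns and "id" in phen.columns:
        merged = geno.merge(phen, on="id", how="inner")
        geno = merged[[c for c in geno.columns if c != "id"]]
        phen = merged[[c for c in phen.columns if c != "id"]]
    phen_col = [c for c in phen.columns if c != "id"][0]
    code_map = {"A": 0.0, "H": 1.0, "B": 2.0}
    out = {}
    for col in geno.columns:
        if col == "id":
            continue
        series = geno[col]
        if series.dtype == object:
            series = series.str.strip().replace({"-": np.nan, "NA": np.nan, "": np.nan})
            series = series.map(lambda v: code_map.get(v, v))
        out[col] = pd.to_numeric(series, errors="raise").astype(float)
    return pd.DataFrame(out), phen[phen_col].astype(float).to_numpy()
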