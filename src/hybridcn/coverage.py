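"""Per-bin mean read depth from a BAM alignment, as median-centered log2.

Depth of a bin is the sum over its base positions of aligned read coverage
(CIGAR M/=/X blocks only), divided by bin length.  Reads that are unmapped,
secondary, QC-fail or duplicate are excluded unless the corresponding flag
allows them; a mapping-quality floor is configurable.  Empty bins receive a
small pseudo-depth so log2 stays finite and bin sets stay aligned across
samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .tables import BinTable, TableError


@dataclass
class DepthParams:
    min_mapq: int = 0
    count_duplicates: bool = False
    count_secondary: bool = False
    log2_floor_depth: float = 0.01

    def __post_init__(self):
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")
        if self.log2_floor_depth <= 0:
            raise ValueError("log2_floor_depth must be positive")


def _read_passes(read: pysam.AlignedSegment, params: DepthParams) -> bool:
    if read.is_unmapped or read.is_qcfail:
        return False
    if read.is_secondary and not params.count_secondary:
        return False
    if read.is_duplicate and not params.count_duplicates:
        return False
    if read.mapping_quality < params.min_mapq:
        return False
    return True


def bin_depths(
    bam_path,
    bins: BinTable,
    params: DepthParams | None = None,
    sample_id: str | None = None,
) -> BinTable:
    """Mean aligned-base depth per bin, log2-transformed and median-centered.

    The BAM must be coordinate-sorted and indexed.  Bins on chromosomes
    absent from the alignment header get depth 0 with a warning.
    """
    params = params or DepthParams()
    rows = []
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        if not bam.has_index():
            raise TableError(f"{bam_path}: missing BAM index")
        refs = set(bam.references)
        warned: set[str] = set()
        for chrom, start, end in zip(bins.chromosome, bins.start, bins.end):
            if chrom not in refs:
                if chrom not in warned:
                    warnings.warn(f"chromosome {chrom} absent from {bam_path}", stacklevel=2)
                    warned.add(chrom)
                rows.append(0.0)
                continue
            covered = 0
            for read in bam.fetch(chrom, int(start), int(end)):
                if not _read_passes(read, params):
                    continue
                for bs, be in read.get_blocks():
                    lo = max(bs, start)
                    hi = min(be, end)
                    if hi > lo:
                        covered += hi - lo
            rows.append(covered / (end - start))
    return depths_to_table(bins, np.asarray(rows, dtype=float), params, sample_id)


def depths_to_table(
    bins: BinTable,
    depths: np.ndarray,
    params: DepthParams | None = None,
    sample_id: str | None = None,
) -> BinTable:
    """Wrap raw per-bin depths into a centered log2 CoverageTable."""
    params = params or DepthParams()
    if len(depths) != len(bins):
        raise TableError("depth vector does not match bin count")
    df = bins.data[["chromosome", "start", "end", "gene"]].copy()
    df["depth"] = depths
    df["log2"] = np.log2(np.maximum(depths, params.log2_floor_depth))
    table = BinTable(df, role="coverage", sample_id=sample_id)
    return table.median_center(autosomes_only=True)


def import_picard_coverage(
    path, bins: BinTable, params: DepthParams | None = None, sample_id: str | None = None
) -> BinTable:
    """Import a Picard CalculateHsMetrics per-target coverage table.

    Picard coordinates are 1-based inclusive; they are converted to 0-based
    half-open and must then match the given bins exactly.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    df.columns = [c.lower() for c in df.columns]
    required = {"chrom", "start", "end", "mean_coverage"}
    if not required.issubset(df.columns):
        raise TableError(f"{path}: expected columns {sorted(required)}")
    if len(df) == 0:
        raise TableError(f"{path}: no coverage rows")
    df["start"] = df["start"].astype(int) - 1  # to half-open
    key = list(zip(df["chrom"], df["start"], df["end"].astype(int)))
    by_coord = dict(zip(key, df["mean_coverage"].astype(float)))
    depths = np.empty(len(bins))
    for i, (chrom, s, e) in enumerate(zip(bins.chromosome, bins.start, bins.end)):
        try:
            depths[i] = by_coord[(chrom, s, e)]
        except KeyError:
            raise TableError(
                f"{path}: no coverage row matching bin {chrom}:{s}-{e}"
            ) from None
    return depths_to_table(bins, depths, params, sample_id)
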