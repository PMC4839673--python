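"""Construction of on-target and off-target ("antitarget") bins.

Capture baits give exon-scale on-target bins; the gaps between them are
carved into large off-target bins (~100 kb) so that on- and off-target bins
collect comparable read counts.  Off-target regions are intersected with an
optional set of sequencing-accessible intervals to exclude centromeres,
telomeres and unmappable repeats.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import ANTITARGET_LABEL, BinTable, TableError, chrom_sort_key, sort_genomic


@dataclass
class BinningParams:
    """Bin sizing parameters (bp).

    avg_antitarget_bin is typically the average target size times the
    on-target fold enrichment, so on- and off-target bins catch similar
    read counts; min_antitarget_bin discards gaps too small to estimate
    copy number from sparse off-target reads.
    """

    avg_target_bin: int = 267
    avg_antitarget_bin: int = 150_000
    min_antitarget_bin: int = 10_000

    def __post_init__(self):
        if min(self.avg_target_bin, self.avg_antitarget_bin, self.min_antitarget_bin) <= 0:
            raise ValueError("bin sizes must be positive")
        if self.min_antitarget_bin > self.avg_antitarget_bin:
            raise ValueError("min_antitarget_bin exceeds avg_antitarget_bin")


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent-key intervals per chromosome, joining names."""
    if len(df) == 0:
        return df.copy()
    df = sort_genomic(df)
    has_gene = "gene" in df.columns
    rows = []
    for chrom, sub in df.groupby("chromosome", sort=False):
        cur_s = cur_e = None
        names: list[str] = []
        for s, e, g in zip(
            sub["start"], sub["end"], sub["gene"] if has_gene else ["-"] * len(sub)
        ):
            if cur_s is None:
                cur_s, cur_e, names = s, e, [str(g)]
            elif s < cur_e:  # strict overlap only; abutting targets stay apart
                cur_e = max(cur_e, e)
                if str(g) not in names:
                    names.append(str(g))
            else:
                rows.append((chrom, cur_s, cur_e, ",".join(names)))
                cur_s, cur_e, names = s, e, [str(g)]
        rows.append((chrom, cur_s, cur_e, ",".join(names)))
    out = pd.DataFrame(rows, columns=["chromosome", "start", "end", "gene"])
    return sort_genomic(out)


def _equal_partition(start: int, end: int, n: int) -> list[tuple[int, int]]:
    """Split [start, end) into n integer pieces whose sizes differ by <= 1 bp."""
    length = end - start
    edges = [start + round(i * length / n) for i in range(n + 1)]
    return [(edges[i], edges[i + 1]) for i in range(n)]


def split_targets(targets: pd.DataFrame, avg_target_bin: int = 267) -> BinTable:
    """Subdivide (merged) capture targets into bins near avg_target_bin bp.

    A target of length L becomes k = max(1, round(L / avg)) bins of equal
    size (+-1 bp); target names propagate to every derived bin.
    """
    if len(targets) == 0:
        raise TableError("empty target set")
    if avg_target_bin <= 0:
        raise ValueError("avg_target_bin must be positive")
    merged = merge_intervals(targets)
    rows = []
    for chrom, s, e, gene in zip(
        merged["chromosome"], merged["start"], merged["end"], merged["gene"]
    ):
        k = max(1, round((e - s) / avg_target_bin))
        for bs, be in _equal_partition(int(s), int(e), k):
            rows.append((chrom, bs, be, gene))
    df = pd.DataFrame(rows, columns=["chromosome", "start", "end", "gene"])
    return BinTable(df, role="target")


def antitarget_bins(
    targets: pd.DataFrame,
    access: pd.DataFrame | None = None,
    chrom_lengths: dict[str, int] | None = None,
    params: BinningParams | None = None,
) -> BinTable:
    """Carve off-target gaps between capture targets into large equal bins.

    Each contiguous accessible off-target region of length L >= the minimum
    gets k = max(1, round(L / avg)) bins differing by at most 1 bp, so the
    average bin size within the region is as close as possible to the
    requested size.  Without access regions, chromosome extents come from
    ``chrom_lengths``; if neither is given, only interior gaps between
    targets are binned and chromosome ends are skipped with a warning.
    """
    params = params or BinningParams()
    if len(targets) == 0:
        raise TableError("empty target set")
    merged = merge_intervals(targets)

    # accessible domain per chromosome
    domains: dict[str, list[tuple[int, int]]] = {}
    if access is not None and len(access):
        acc = sort_genomic(access)
        for chrom, sub in acc.groupby("chromosome", sort=False):
            domains[chrom] = list(zip(sub["start"].astype(int), sub["end"].astype(int)))
    elif chrom_lengths is not None:
        domains = {c: [(0, int(n))] for c, n in chrom_lengths.items()}

    rows = []
    for chrom, sub in merged.groupby("chromosome", sort=False):
        tgt = list(zip(sub["start"].astype(int), sub["end"].astype(int)))
        if domains:
            if chrom not in domains:
                raise TableError(f"targets on unknown chromosome {chrom!r}")
            dom = domains[chrom]
        else:
            warnings.warn(
                f"no access regions or chromosome lengths: skipping the ends of {chrom}",
                stacklevel=2,
            )
            dom = [(tgt[0][0], tgt[-1][1])]
        gaps = _subtract(dom, tgt)
        for gs, ge in gaps:
            length = ge - gs
            if length < params.min_antitarget_bin:
                continue
            k = max(1, round(length / params.avg_antitarget_bin))
            for bs, be in _equal_partition(gs, ge, k):
                rows.append((chrom, bs, be, ANTITARGET_LABEL))
    df = pd.DataFrame(rows, columns=["chromosome", "start", "end", "gene"])
    return BinTable(df, role="target")


def _subtract(
    domain: list[tuple[int, int]], remove: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Sorted disjoint intervals of ``domain`` minus ``remove``."""
    out = []
    for ds, de in domain:
        pos = ds
        for rs, re in remove:
            if re <= pos or rs >= de:
                continue
            if rs > pos:
                out.append((pos, min(rs, de)))
            pos = max(pos, re)
            if pos >= de:
                break
        if pos < de:
            out.append((pos, de))
    return out


def suggest_antitarget_size(avg_target_size: float, fold_enrichment: float) -> int:
    """Off-target bin size matching on-target read counts: size x enrichment.

    Returned in bp, rounded to the nearest kilobase with a 1 kb floor.
    """
    if avg_target_size <= 0 or fold_enrichment <= 0:
        raise ValueError("avg_target_size and fold_enrichment must be positive")
    kb = round(avg_target_size * fold_enrichment / 1000)
    return max(1, kb) * 1000
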