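"""Import/export bridges: SEG, BED and Picard interval lists.

SEG (GenePattern / IGV) rows are 1-based inclusive and carry the log2
segment mean; the native tables are 0-based half-open, so coordinates are
shifted on the way through.  Interval lists (1-based inclusive, with or
without an @-prefixed SAM-style header) are converted to half-open on
import; BED passes through unchanged.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .tables import BinTable, SegmentTable, TableError, sort_genomic

SEG_COLUMNS = ["sample", "chromosome", "start", "end", "num_mark", "seg_mean"]


def export_seg(segments: SegmentTable | list[SegmentTable], path) -> None:
    """Write one or more samples' segments as a SEG file (seg.mean = log2)."""
    if isinstance(segments, SegmentTable):
        segments = [segments]
    frames = []
    for k, seg in enumerate(segments):
        df = seg.data
        frames.append(
            pd.DataFrame(
                {
                    "sample": seg.sample_id or f"sample_{k + 1}",
                    "chromosome": df["chromosome"],
                    "start": df["start"] + 1,  # SEG is 1-based inclusive
                    "end": df["end"],
                    "num_mark": df["n_bins"] if "n_bins" in df.columns else 1,
                    "seg_mean": df["log2"],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.columns = ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]
    out.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def import_seg(path) -> dict[str, SegmentTable]:
    """Read a SEG file into one SegmentTable per sample id."""
    df = pd.read_csv(path, sep="\t", dtype={1: str})
    cols = {c.lower().replace(".", "_"): c for c in df.columns}
    mapping = {
        "id": "sample",
        "chrom": "chromosome",
        "loc_start": "start",
        "loc_end": "end",
        "num_mark": "n_bins",
        "seg_mean": "log2",
    }
    missing = [k for k in mapping if k not in cols]
    if missing:
        raise TableError(f"{path}: missing SEG column(s) {missing}")
    df = df.rename(columns={cols[k]: v for k, v in mapping.items()})
    if len(df) and not pd.api.types.is_numeric_dtype(df["log2"]):
        raise TableError(f"{path}: non-numeric seg.mean values")
    out = {}
    for sample, sub in df.groupby("sample", sort=False):
        sub = sub.copy()
        sub["chromosome"] = sub["chromosome"].astype(str)
        sub["start"] = sub["start"].astype(int) - 1  # back to half-open
        out[str(sample)] = SegmentTable(
            sub[["chromosome", "start", "end", "log2", "n_bins"]], sample_id=str(sample)
        )
    return out


def export_bed(table: BinTable | SegmentTable, path, name_column: str | None = None) -> None:
    """Write bins or segments as BED4 (name = gene label, or cn/log2)."""
    df = table.data
    if name_column is None:
        name_column = "gene" if "gene" in df.columns else "log2"
    bed = df[["chromosome", "start", "end"]].copy()
    bed["name"] = df[name_column] if name_column in df.columns else "-"
    sort_genomic(bed).to_csv(path, sep="\t", index=False, header=False, lineterminator="\n")


def import_intervals(path) -> pd.DataFrame:
    """Read targets from BED or a Picard/GATK interval list.

    Interval-list rows (``chrom  start  end  [strand]  [name]``, 1-based
    inclusive, optional @-header) are converted to 0-based half-open; BED
    passes through.  Strand is ignored with a warning.  Returns a sorted
    DataFrame with chromosome/start/end/gene columns.
    """
    rows = []
    is_interval_list = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("@"):
                is_interval_list = True
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise TableError(f"{path}:{lineno}: expected at least 3 columns")
            rows.append((lineno, fields))
    if not rows:
        return pd.DataFrame(columns=["chromosome", "start", "end", "gene"])
    # interval lists put strand (+/-) in column 4
    if not is_interval_list:
        is_interval_list = any(
            len(f) >= 4 and f[3] in ("+", "-") for _, f in rows
        )
    saw_strand = False
    recs = []
    for lineno, f in rows:
        try:
            start, end = int(f[1]), int(f[2])
        except ValueError:
            raise TableError(f"{path}:{lineno}: non-integer coordinates") from None
        if is_interval_list:
            start -= 1  # 1-based inclusive -> half-open
            name = f[4] if len(f) > 4 else "-"
            if len(f) > 3 and f[3] in ("+", "-"):
                saw_strand = True
        else:
            name = f[3] if len(f) > 3 else "-"
        recs.append((f[0], start, end, name))
    if saw_strand:
        warnings.warn(f"{path}: strand column ignored", stacklevel=2)
    df = pd.DataFrame(recs, columns=["chromosome", "start", "end", "gene"])
    return sort_genomic(df)
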