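"""Binned genomic value tables and the native tab-separated format.

Every stage of the pipeline speaks the same BED-like table of genomic bins:
``chromosome  start  end  gene  log2  [depth gc rmask spread weight]``.
Coordinates are 0-based half-open throughout (BED convention); Picard
interval lists are converted at import only.  Tables are kept sorted in
natural chromosome order (chr1 < chr2 < chr10) and validated against
within-chromosome overlap.
"""

from __future__ import annotations

import io
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ANTITARGET_LABEL = "Antitarget"

#: default set of chromosome names excluded from "autosome" statistics
SEX_CHROMS = frozenset({"X", "Y", "chrX", "chrY"})

#: canonical column order of the native format
ALL_COLUMNS = (
    "chromosome",
    "start",
    "end",
    "gene",
    "log2",
    "depth",
    "gc",
    "rmask",
    "spread",
    "weight",
)
CORE_COLUMNS = ("chromosome", "start", "end")

SEGMENT_COLUMNS = ("chromosome", "start", "end", "log2", "n_bins", "weight", "cn")

#: spread value marking bins the reference flags as unreliable
SPREAD_SENTINEL = np.inf


class TableError(ValueError):
    """Raised for malformed or invariant-violating tables."""


def chrom_sort_key(chrom: str):
    """Natural sort key: chr1 < chr2 < chr10 < chrX; non-numeric names last."""
    body = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if body.isdigit():
        return (0, int(body), "")
    return (1, 0, body)


def sort_genomic(df: pd.DataFrame) -> pd.DataFrame:
    """Sort rows by (natural chromosome, start, end), resetting the index."""
    key = df["chromosome"].map(chrom_sort_key)
    order = sorted(range(len(df)), key=lambda i: (key.iat[i], df["start"].iat[i], df["end"].iat[i]))
    return df.iloc[order].reset_index(drop=True)


def is_autosome(chrom: str, sex_chroms: frozenset[str] = SEX_CHROMS) -> bool:
    return chrom not in sex_chroms


def _validate(df: pd.DataFrame, allow_overlap: bool = False) -> None:
    for col in CORE_COLUMNS:
        if col not in df.columns:
            raise TableError(f"missing required column {col!r}")
    if len(df) == 0:
        return
    if (df["chromosome"].astype(str).str.len() == 0).any():
        raise TableError("empty chromosome name")
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    if (starts < 0).any():
        raise TableError("negative start coordinate")
    if (starts >= ends).any():
        i = int(np.argmax(starts >= ends))
        raise TableError(
            f"empty or inverted interval at row {i}: "
            f"{df['chromosome'].iat[i]}:{starts[i]}-{ends[i]}"
        )
    for col in ("gc", "rmask"):
        if col in df.columns:
            vals = df[col].to_numpy(dtype=float)
            ok = np.isnan(vals) | ((vals >= 0.0) & (vals <= 1.0))
            if not ok.all():
                raise TableError(f"{col} outside [0, 1]")
    if "weight" in df.columns:
        w = df["weight"].to_numpy(dtype=float)
        if (w[~np.isnan(w)] < 0).any():
            raise TableError("negative weight")
    if not allow_overlap:
        for chrom, sub in df.groupby("chromosome", sort=False):
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            if len(s) > 1 and (s[1:] < e[:-1]).any():
                i = int(np.argmax(s[1:] < e[:-1]))
                raise TableError(
                    f"overlapping bins on {chrom}: "
                    f"[{s[i]},{e[i]}) and [{s[i + 1]},{e[i + 1]})"
                )


class BinTable:
    """An ordered, validated table of genomic bins.

    Parameters
    ----------
    data : pandas.DataFrame
        Must carry chromosome/start/end; other native columns optional and
        unknown columns are preserved.
    role : str
        One of ``coverage``, ``ratio``, ``reference``, ``target`` — a marker
        only; it decides which optional columns downstream stages require.
    sample_id : str, optional
        Identifier carried through to exports.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        role: str = "ratio",
        sample_id: str | None = None,
        validate: bool = True,
    ):
        df = data.reset_index(drop=True).copy()
        if "start" in df.columns:
            df["start"] = df["start"].astype(np.int64)
            df["end"] = df["end"].astype(np.int64)
        if "gene" not in df.columns:
            df["gene"] = "-"
        df = sort_genomic(df)
        if validate:
            _validate(df)
        # keep native columns in canonical order, extras after
        native = [c for c in ALL_COLUMNS if c in df.columns]
        extras = [c for c in df.columns if c not in ALL_COLUMNS]
        self.data = df[native + extras]
        self.role = role
        self.sample_id = sample_id
        self.n_controls: int | None = None  # populated on reference profiles

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other) -> bool:
        return isinstance(other, BinTable) and self.data.equals(other.data)

    def copy(self) -> "BinTable":
        out = BinTable(self.data, self.role, self.sample_id, validate=False)
        out.n_controls = self.n_controls
        return out

    @property
    def chromosome(self) -> pd.Series:
        return self.data["chromosome"]

    @property
    def start(self) -> np.ndarray:
        return self.data["start"].to_numpy()

    @property
    def end(self) -> np.ndarray:
        return self.data["end"].to_numpy()

    @property
    def log2(self) -> np.ndarray:
        return self.data["log2"].to_numpy(dtype=float)

    def autosome_mask(self, sex_chroms: frozenset[str] = SEX_CHROMS) -> np.ndarray:
        return self.data["chromosome"].map(lambda c: is_autosome(c, sex_chroms)).to_numpy()

    def on_target_mask(self) -> np.ndarray:
        return (self.data["gene"] != ANTITARGET_LABEL).to_numpy()

    # -- operations --------------------------------------------------------
    def median_center(
        self,
        autosomes_only: bool = True,
        sex_chroms: frozenset[str] = SEX_CHROMS,
    ) -> "BinTable":
        """Shift log2 so the median over (autosomal) bins is exactly zero."""
        if len(self.data) == 0:
            raise TableError("cannot center an empty table")
        if "log2" not in self.data.columns:
            raise TableError("table has no log2 column")
        mask = self.autosome_mask(sex_chroms) if autosomes_only else np.ones(len(self.data), bool)
        if not mask.any():
            raise TableError("no autosomal bins to center on")
        out = self.copy()
        out.data["log2"] = self.log2 - np.median(self.log2[mask])
        return out

    # -- I/O ----------------------------------------------------------------
    def write(self, path) -> None:
        write_table(self, path)

    @classmethod
    def read(cls, path, role: str = "ratio", sample_id: str | None = None) -> "BinTable":
        return read_table(path, role=role, sample_id=sample_id)


def _format_frame(df: pd.DataFrame) -> str:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.6g}")
    buf = io.StringIO()
    out.to_csv(buf, sep="\t", index=False, lineterminator="\n")
    return buf.getvalue()


def write_table(table, path) -> None:
    """Write a BinTable or SegmentTable to the native TSV format.

    Reals are printed with 6 significant digits, so a read/write round trip
    is exact for integer fields and stable at the printed precision for
    reals.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_format_frame(table.data))


def read_table(path, role: str = "ratio", sample_id: str | None = None) -> BinTable:
    """Read a native table; requires at least chromosome/start/end columns."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    except pd.errors.ParserError as exc:
        raise TableError(f"malformed table {path}: {exc}") from None
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise TableError(f"{path}: missing column(s) {missing}")
    return BinTable(df, role=role, sample_id=sample_id)


class SegmentTable:
    """Contiguous constant-copy-ratio segments.

    Segments within a chromosome are sorted and non-overlapping; ``n_bins``
    counts member bins, ``weight`` sums their weights and ``cn`` (optional)
    is the called integer copy number.
    """

    def __init__(self, data: pd.DataFrame, sample_id: str | None = None, validate: bool = True):
        df = data.reset_index(drop=True).copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if "n_bins" in df.columns:
            df["n_bins"] = df["n_bins"].astype(np.int64)
        df = sort_genomic(df)
        if validate:
            _validate(df)
            if "n_bins" in df.columns and (df["n_bins"].to_numpy() <= 0).any():
                raise TableError("segment with n_bins <= 0")
        known = [c for c in SEGMENT_COLUMNS if c in df.columns]
        extras = [c for c in df.columns if c not in SEGMENT_COLUMNS]
        self.data = df[known + extras]
        self.sample_id = sample_id

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other) -> bool:
        return isinstance(other, SegmentTable) and self.data.equals(other.data)

    def copy(self) -> "SegmentTable":
        return SegmentTable(self.data, self.sample_id, validate=False)

    @property
    def log2(self) -> np.ndarray:
        return self.data["log2"].to_numpy(dtype=float)

    def write(self, path) -> None:
        write_table(self, path)

    @classmethod
    def read(cls, path, sample_id: str | None = None) -> "SegmentTable":
        df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
        missing = [c for c in CORE_COLUMNS if c not in df.columns]
        if missing:
            raise TableError(f"{path}: missing column(s) {missing}")
        return cls(df, sample_id=sample_id)
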