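"""Purity rescaling, absolute copy-number calling, and tabular reports.

A tumor sample is a mixture of tumor cells (fraction = purity) and normal
cells; the observed linear copy ratio is r_obs = purity * r_tumor +
(1 - purity).  Inverting this mixture recovers the tumor's own ratio, which
rounds to an integer copy number given the chromosome's normal ploidy.
Reports summarize gene-level gains/losses, intragenic breakpoints, and
residual noise of bins around their segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import ANTITARGET_LABEL, BinTable, SegmentTable, TableError

#: log2 floor used to represent a homozygous (copy 0) state finitely
MIN_LOG2 = -5.0


@dataclass
class CallParams:
    purity: float = 1.0
    ploidy: int = 2
    center_method: str = "median"
    thresholds: tuple[float, ...] | None = None

    def __post_init__(self):
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")
        if self.ploidy <= 0:
            raise ValueError("ploidy must be positive")
        if self.thresholds is not None and list(self.thresholds) != sorted(
            set(self.thresholds)
        ):
            raise ValueError("thresholds must be strictly ascending")


def rescale_purity(
    segments: SegmentTable, purity: float, ploidy: int = 2, min_log2: float = MIN_LOG2
) -> SegmentTable:
    """Remove normal-cell dilution from segment log2 ratios.

    r_tumor = (2^log2 - (1 - purity)) / purity, floored at 2^min_log2 so a
    fully deleted segment stays representable; purity 1 is the identity.
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    out = segments.copy()
    r_obs = 2.0 ** out.log2
    r_tumor = (r_obs - (1.0 - purity)) / purity
    out.data["log2"] = np.log2(np.maximum(r_tumor, 2.0**min_log2))
    return out


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


def _kde_mode(values: np.ndarray, weights: np.ndarray) -> float:
    """Dominant mode by Gaussian KDE (Silverman bandwidth), grid argmax."""
    if len(values) == 1:
        return float(values[0])
    kde = stats.gaussian_kde(values, bw_method="silverman", weights=weights)
    grid = np.linspace(values.min() - 0.5, values.max() + 0.5, 2001)
    return float(grid[np.argmax(kde(grid))])


def _biweight_location(values: np.ndarray, c: float = 6.0, eps: float = 1e-9) -> float:
    """Tukey's biweight location, iterated to convergence."""
    m = float(np.median(values))
    for _ in range(20):
        mad = np.median(np.abs(values - m)) + eps
        u = (values - m) / (c * mad)
        mask = np.abs(u) < 1
        if not mask.any():
            return m
        wt = (1 - u[mask] ** 2) ** 2
        new = float(np.sum(values[mask] * wt) / np.sum(wt))
        if abs(new - m) < eps:
            return new
        m = new
    return m


CENTER_METHODS = ("median", "mean", "mode", "biweight")


def recenter(segments: SegmentTable, method: str = "median") -> SegmentTable:
    """Shift all segment log2 so the chosen (bin-count-weighted) central
    tendency is zero."""
    if len(segments) == 0:
        raise TableError("cannot recenter an empty segment table")
    if method not in CENTER_METHODS:
        raise TableError(f"unknown centering method {method!r}")
    vals = segments.log2
    w = segments.data["n_bins"].to_numpy(dtype=float)
    if method == "median":
        shift = _weighted_median(vals, w)
    elif method == "mean":
        shift = float(np.average(vals, weights=w))
    elif method == "mode":
        shift = _kde_mode(vals, w)
    else:
        shift = _biweight_location(np.repeat(vals, w.astype(int)))
    out = segments.copy()
    out.data["log2"] = vals - shift
    return out


def call_absolute(
    segments: SegmentTable,
    ploidy: int = 2,
    thresholds: tuple[float, ...] | None = None,
    sex_chrom_ploidy: dict[str, int] | None = None,
) -> SegmentTable:
    """Assign an integer copy number to every segment.

    By default cn = round(ploidy * 2^log2), floored at 0.  With explicit
    ascending thresholds, cn is the number of thresholds the segment's log2
    exceeds (state 0 below the first cutoff).  ``sex_chrom_ploidy`` can
    override the normal ploidy per chromosome (e.g. {"chrX": 1, "chrY": 1}
    for a male sample).
    """
    out = segments.copy()
    log2 = out.log2
    if thresholds is not None:
        cuts = np.asarray(thresholds, dtype=float)
        if not np.all(np.diff(cuts) > 0):
            raise TableError("thresholds must be strictly ascending")
        cn = (log2[:, None] > cuts[None, :]).sum(axis=1)
    else:
        pl = np.full(len(out), float(ploidy))
        if sex_chrom_ploidy:
            for chrom, p in sex_chrom_ploidy.items():
                pl[(out.data["chromosome"] == chrom).to_numpy()] = p
        cn = np.maximum(0, np.round(pl * 2.0**log2)).astype(int)
    out.data["cn"] = cn.astype(int)
    return out


# ---------------------------------------------------------------------------
# reports


def _gene_spans(ratio: BinTable) -> pd.DataFrame:
    """Footprint of each gene label across its (on-target) bins."""
    df = ratio.data
    on = df[df["gene"] != ANTITARGET_LABEL]
    rows = []
    for gene, sub in on.groupby("gene", sort=False):
        for chrom, csub in sub.groupby("chromosome", sort=False):
            rows.append(
                {
                    "gene": gene,
                    "chromosome": chrom,
                    "start": int(csub["start"].min()),
                    "end": int(csub["end"].max()),
                    "n_bins": len(csub),
                }
            )
    return pd.DataFrame(rows, columns=["gene", "chromosome", "start", "end", "n_bins"])


def gainloss(
    ratio: BinTable, segments: SegmentTable, threshold: float = 0.58
) -> pd.DataFrame:
    """Genes whose covering segment log2 magnitude reaches the threshold.

    A gene split across several segments is reported once per overlapping
    segment.  The default 0.58 corresponds to a 1.5x change — a single
    copy gained at diploid.
    """
    spans = _gene_spans(ratio)
    seg = segments.data
    rows = []
    for _, g in spans.iterrows():
        hits = seg[
            (seg["chromosome"] == g["chromosome"])
            & (seg["start"] < g["end"])
            & (seg["end"] > g["start"])
        ]
        for _, s in hits.iterrows():
            if abs(s["log2"]) >= threshold:
                rows.append(
                    {
                        "gene": g["gene"],
                        "chromosome": g["chromosome"],
                        "start": g["start"],
                        "end": g["end"],
                        "n_bins": g["n_bins"],
                        "log2": s["log2"],
                        "direction": "gain" if s["log2"] > 0 else "loss",
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["gene", "chromosome", "start", "end", "n_bins", "log2", "direction"],
    )


def breaks(ratio: BinTable, segments: SegmentTable) -> pd.DataFrame:
    """Every (gene, breakpoint) pair where a segment boundary falls strictly
    inside the gene's bin span — a possible structural break."""
    spans = _gene_spans(ratio)
    seg = segments.data
    rows = []
    for _, g in spans.iterrows():
        sub = seg[seg["chromosome"] == g["chromosome"]]
        # interior boundaries between consecutive segments
        for left, right in zip(sub.itertuples(), sub.iloc[1:].itertuples()):
            bp = right.start
            if g["start"] < bp < g["end"]:
                rows.append(
                    {
                        "gene": g["gene"],
                        "chromosome": g["chromosome"],
                        "breakpoint": int(bp),
                        "log2_left": left.log2,
                        "log2_right": right.log2,
                    }
                )
    return pd.DataFrame(
        rows, columns=["gene", "chromosome", "breakpoint", "log2_left", "log2_right"]
    )


def _biweight_midvariance(values: np.ndarray, c: float = 9.0, eps: float = 1e-9) -> float:
    m = np.median(values)
    mad = np.median(np.abs(values - m)) + eps
    u = (values - m) / (c * mad)
    mask = np.abs(u) < 1
    if not mask.any():
        return 0.0
    top = np.sum(((values[mask] - m) ** 2) * (1 - u[mask] ** 2) ** 4)
    bot = np.sum((1 - u[mask] ** 2) * (1 - 5 * u[mask] ** 2))
    n = len(values)
    return float(n * top / bot**2) if bot != 0 else 0.0


def _residuals(ratio: BinTable, segments: SegmentTable) -> np.ndarray:
    """Bin log2 minus the log2 of the containing segment (NaN if uncovered)."""
    res = np.full(len(ratio), np.nan)
    df = ratio.data
    seg = segments.data
    for i, (chrom, start, end, val) in enumerate(
        zip(df["chromosome"], df["start"], df["end"], df["log2"])
    ):
        hit = seg[
            (seg["chromosome"] == chrom) & (seg["start"] < end) & (seg["end"] > start)
        ]
        if len(hit):
            res[i] = val - hit["log2"].iat[0]
    return res


def residual_stats(residuals: np.ndarray) -> dict[str, float]:
    r = residuals[~np.isnan(residuals)]
    if len(r) == 0:
        return {"mad": np.nan, "spread": np.nan, "iqr": np.nan, "bivar": np.nan}
    return {
        "mad": float(np.median(np.abs(r - np.median(r)))),
        "spread": float(stats.median_abs_deviation(r, scale="normal")),
        "iqr": float(np.percentile(r, 75) - np.percentile(r, 25)),
        "bivar": _biweight_midvariance(r),
    }


def residual_metrics(ratio: BinTable, segments: SegmentTable) -> dict[str, float]:
    """Per-sample robust statistics of bin residuals around segment means:
    unscaled MAD, normal-scaled MAD ('spread'), IQR and biweight
    midvariance."""
    return residual_stats(_residuals(ratio, segments))


def segment_metrics(ratio: BinTable, segments: SegmentTable) -> pd.DataFrame:
    """residual_metrics computed per segment over its member bins."""
    df = ratio.data
    rows = []
    for _, s in segments.data.iterrows():
        member = df[
            (df["chromosome"] == s["chromosome"])
            & (df["start"] >= s["start"])
            & (df["end"] <= s["end"])
        ]
        st = residual_stats(member["log2"].to_numpy(dtype=float) - s["log2"])
        rows.append({**s.to_dict(), **st})
    return pd.DataFrame(rows)


def fish_to_log2(mean_signal_count: float, ploidy: float) -> float:
    """Convert a mean FISH nuclear signal count to a log2 copy ratio
    relative to the cell's ploidy: log2(count) - log2(ploidy)."""
    if mean_signal_count <= 0 or ploidy <= 0:
        raise ValueError("signal count and ploidy must be positive")
    return float(np.log2(mean_signal_count) - np.log2(ploidy))
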