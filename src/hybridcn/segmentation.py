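"""Change-point segmentation of weighted log2 copy ratios.

Two backends are provided, both implemented here:

* Circular binary segmentation (CBS): recursively finds the arc of bins
  whose weighted mean most differs from the rest of the (circularized)
  segment, measured by a weighted two-sample t statistic maximized over
  all arc boundaries; a split is accepted when a permutation test of the
  bin values within the segment gives p < alpha.
* A Haar-wavelet segmentation: log2 values are convolved with Haar step
  kernels at dyadic scales; local maxima of the normalized statistic that
  pass a false-discovery threshold become breakpoints, merged across
  scales keeping the finest localization.

An optional pre-filter zeroes the weight of isolated outlier bins, defined
as exceeding a fixed multiple of the 95th percentile of absolute deviation
from the local median in a rolling window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .tables import BinTable, SegmentTable


@dataclass
class SegmentationParams:
    method: str = "cbs"
    alpha: float = 0.01
    n_perm: int = 100
    seed: int = 0
    haar_fdr: float = 0.001
    max_scale: int = 6
    outlier_window: int = 50
    outlier_multiple: float = 4.0
    min_bins_per_segment: int = 3

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.outlier_multiple <= 1:
            raise ValueError("outlier_multiple must be > 1")
        if self.method not in ("cbs", "haar"):
            raise ValueError(f"unknown segmentation method {self.method!r}")


# ---------------------------------------------------------------------------
# outlier filtering


def filter_outliers(
    ratio: BinTable, window: int = 50, multiple: float = 4.0
) -> BinTable:
    """Zero the weight of extreme isolated bins; coordinates are retained.

    Within a rolling window the 95th percentile of |log2 - window median|
    sets the local scale; bins whose deviation exceeds ``multiple`` times
    that scale are excluded from fitting by setting their weight to 0.
    """
    if window < 5:
        raise ValueError("window must be >= 5")
    out = ratio.copy()
    if "weight" not in out.data.columns:
        out.data["weight"] = 1.0
    log2 = out.log2
    n = len(log2)
    if n == 0:
        return out
    # lower-interpolation percentile: a lone extreme value cannot raise the
    # threshold of its own window
    if n <= window:
        med = np.median(log2)
        dev = np.abs(log2 - med)
        cut = multiple * np.percentile(dev, 95, method="lower")
        flag = dev > cut if cut > 0 else np.zeros(n, bool)
    else:
        s = pd.Series(log2)
        med = s.rolling(window, center=True, min_periods=1).median().to_numpy()
        dev = np.abs(log2 - med)
        q95 = (
            pd.Series(dev)
            .rolling(window, center=True, min_periods=1)
            .quantile(0.95, interpolation="lower")
            .to_numpy()
        )
        cut = multiple * q95
        flag = (dev > cut) & (cut > 0)
    w = out.data["weight"].to_numpy(dtype=float)
    w[flag] = 0.0
    out.data["weight"] = w
    return out


# ---------------------------------------------------------------------------
# circular binary segmentation


_TRIU_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _triu(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _TRIU_CACHE:
        if len(_TRIU_CACHE) > 8:
            _TRIU_CACHE.clear()
        _TRIU_CACHE[n] = np.triu_indices(n, k=0)
    return _TRIU_CACHE[n]


def _max_arc_t(x: np.ndarray, w: np.ndarray) -> tuple[float, int, int]:
    """Maximum weighted two-sample t statistic over all arcs of the circle.

    Returns (t_max, i, j): the arc is bins [i, j); its complement is the
    rest.  O(n^2) via broadcast partial sums.
    """
    n = len(x)
    sw = np.concatenate([[0.0], np.cumsum(w)])
    swx = np.concatenate([[0.0], np.cumsum(w * x)])
    W, SX = sw[-1], swx[-1]
    mean_all = SX / W
    var = float(np.sum(w * (x - mean_all) ** 2) / max(W - 1.0, 1e-12))
    if var <= 0:
        return 0.0, 0, 0
    # arc (i, j): weights/up sums between boundaries i < j
    W1 = sw[None, 1:] - sw[:-1, None]  # [i, j] -> sw[j] - sw[i]
    S1 = swx[None, 1:] - swx[:-1, None]
    iu = _triu(n)  # i <= j-1 -> arcs of length >= 1
    W1 = W1[iu]
    S1 = S1[iu]
    W2 = W - W1
    valid = (W1 > 0) & (W2 > 0)
    t = np.zeros(len(W1))
    m1 = np.divide(S1, W1, out=np.zeros_like(S1), where=valid)
    m2 = np.divide(SX - S1, W2, out=np.zeros_like(S1), where=valid)
    denom = np.sqrt(var) * np.sqrt(
        np.divide(1.0, W1, out=np.full_like(W1, np.inf), where=valid)
        + np.divide(1.0, W2, out=np.full_like(W2, np.inf), where=valid)
    )
    t = np.where(valid, np.abs(m1 - m2) / denom, 0.0)
    k = int(np.argmax(t))
    i, j = iu[0][k], iu[1][k] + 1
    return float(t[k]), int(i), int(j)


def _split_pvalue(
    x: np.ndarray, w: np.ndarray, params: SegmentationParams, rng: np.random.Generator
) -> tuple[float, int, int]:
    """Permutation p-value of the best circular split of one segment."""
    t_obs, i, j = _max_arc_t(x, w)
    if t_obs <= 0:
        return 1.0, i, j
    exceed = 0
    for _ in range(params.n_perm):
        perm = rng.permutation(len(x))
        t_p, _, _ = _max_arc_t(x[perm], w[perm])
        if t_p >= t_obs:
            exceed += 1
    return (exceed + 1) / (params.n_perm + 1), i, j


def _cbs_breakpoints(
    x: np.ndarray, w: np.ndarray, params: SegmentationParams, rng: np.random.Generator
) -> list[int]:
    """Recursive CBS on one chromosome; returns interior breakpoint indices."""
    n = len(x)
    min_n = params.min_bins_per_segment
    if n < 2 * min_n:
        return []
    p, i, j = _split_pvalue(x, w, params, rng)
    if p >= params.alpha:
        return []
    cuts = sorted(
        {c for c in (i, j) if min_n <= c <= n - min_n}
    )
    if not cuts:
        return []
    breaks: list[int] = []
    prev = 0
    for c in cuts + [n]:
        sub = _cbs_breakpoints(x[prev:c], w[prev:c], params, rng)
        breaks.extend(prev + b for b in sub)
        if c < n:
            breaks.append(c)
        prev = c
    return sorted(breaks)


# ---------------------------------------------------------------------------
# Haar-wavelet segmentation


def _haar_breakpoints(x: np.ndarray, params: SegmentationParams) -> list[int]:
    """Breakpoints from Haar step-kernel convolutions at dyadic scales."""
    n = len(x)
    if n < 4:
        return []
    sigma = float(stats.median_abs_deviation(np.diff(x), scale="normal") / np.sqrt(2))
    if sigma <= 0:
        sigma = 1e-12
    csum = np.concatenate([[0.0], np.cumsum(x)])
    candidates: list[tuple[int, int, float]] = []  # (scale, position, |z|)
    scale = 0
    while True:
        h = 2**scale
        if 2 * h > n or scale > params.max_scale:
            break
        pos = np.arange(h, n - h + 1)  # breakpoint before index pos
        left = (csum[pos] - csum[pos - h]) / h
        right = (csum[pos + h] - csum[pos]) / h
        z = np.abs(right - left) * np.sqrt(h / 2.0) / sigma
        # local maxima of |z| along the chromosome at this scale
        for k in range(len(pos)):
            lo, hi = max(0, k - h), min(len(pos), k + h + 1)
            if z[k] == z[lo:hi].max() and z[k] > 0:
                candidates.append((scale, int(pos[k]), float(z[k])))
        scale += 1
    if not candidates:
        return []
    # FDR control over candidate peaks (normal tail p-values)
    zs = np.array([c[2] for c in candidates])
    pvals = 2.0 * stats.norm.sf(zs)
    order = np.argsort(pvals)
    m = len(pvals)
    thresh_rank = -1
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= params.haar_fdr * rank / m:
            thresh_rank = rank
    if thresh_rank < 0:
        return []
    keep = set(order[:thresh_rank])
    accepted = [candidates[i] for i in sorted(keep)]
    # merge across scales: finest scale wins within half a coarse kernel
    accepted.sort(key=lambda c: (c[0], -c[2]))  # finest first, strongest first
    final: list[tuple[int, int]] = []  # (scale, position)
    for scale, pos, _ in accepted:
        if all(abs(pos - p) > 2 ** max(scale, s) for s, p in final):
            final.append((scale, pos))
    return sorted(p for _, p in final)


# ---------------------------------------------------------------------------
# driver


def _segments_from_breaks(
    df: pd.DataFrame, breaks: list[int], fit_mask: np.ndarray
) -> list[dict]:
    bounds = [0] + list(breaks) + [len(df)]
    rows = []
    log2 = df["log2"].to_numpy(dtype=float)
    w = df["weight"].to_numpy(dtype=float)
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg_w = w[a:b]
        seg_x = log2[a:b]
        tot = seg_w.sum()
        mean = float(np.sum(seg_w * seg_x) / tot) if tot > 0 else float(np.mean(seg_x))
        rows.append(
            {
                "chromosome": df["chromosome"].iat[a],
                "start": int(df["start"].iat[a]),
                "end": int(df["end"].iat[b - 1]),
                "log2": mean,
                "n_bins": b - a,
                "weight": float(tot),
            }
        )
    return rows


def segment(ratio: BinTable, params: SegmentationParams | None = None) -> SegmentTable:
    """Segment a ratio table with the configured backend.

    Bins with weight 0 (outliers) are excluded from change-point fitting
    but counted into the covering segment's span.  A fixed seed gives
    bit-identical CBS output.
    """
    params = params or SegmentationParams()
    rng = np.random.default_rng(params.seed)
    df = ratio.data
    if "weight" not in df.columns:
        df = df.assign(weight=1.0)
    rows: list[dict] = []
    chrom_order = df["chromosome"].drop_duplicates().tolist()
    for chrom in chrom_order:
        sub = df[df["chromosome"] == chrom].reset_index(drop=True)
        if len(sub) == 0:
            continue
        fit_mask = sub["weight"].to_numpy(dtype=float) > 0
        fit = sub[fit_mask].reset_index(drop=True)
        if len(fit) == 0:
            continue
        x = fit["log2"].to_numpy(dtype=float)
        w = fit["weight"].to_numpy(dtype=float)
        if params.method == "cbs":
            breaks_fit = _cbs_breakpoints(x, w, params, rng)
        else:
            breaks_fit = _haar_breakpoints(x, params)
        # map breakpoints among fitted bins back to all-bin indices
        fit_idx = np.flatnonzero(fit_mask)
        breaks = [int(fit_idx[b]) for b in breaks_fit]
        rows.extend(_segments_from_breaks(sub, breaks, fit_mask))
    out = pd.DataFrame(
        rows, columns=["chromosome", "start", "end", "log2", "n_bins", "weight"]
    )
    return SegmentTable(out, sample_id=ratio.sample_id)


def segment_cbs(ratio: BinTable, params: SegmentationParams | None = None) -> SegmentTable:
    return segment(ratio, replace(params or SegmentationParams(), method="cbs"))


def segment_haar(ratio: BinTable, params: SegmentationParams | None = None) -> SegmentTable:
    return segment(ratio, replace(params or SegmentationParams(), method="haar"))
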