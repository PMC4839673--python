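"""Systematic coverage-bias covariates and rolling-median detrending.

Three covariates explain most extraneous read-depth variation in hybrid
capture: GC fraction (hybridization/amplification efficiency), the
repeat-masked fraction (variable blocking of repetitive DNA), and target
"density" (loss of depth at bait edges plus gain from the overlapping
flanks of close neighbors).  Each is removed by sorting bins by the
covariate, estimating the trend with a rolling median (or LOWESS / Kaiser
window smoother), and subtracting it.

Scope rules: GC correction applies to on- and off-target bins separately;
the repeat correction to off-target bins only (on-target bins containing
repeats are typically covered entirely by the repeat, leaving no trend to
fit); the density correction to on-target bins only, since it models the
capture chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .tables import BinTable, TableError


@dataclass
class DensityParams:
    """Geometry of the edge-effect model.

    ``flank`` is the one-sided distance f (bp) over which capture efficiency
    ramps linearly from zero (f outside a bait edge) to full (f inside) —
    in effect half the span of a sequence fragment overhanging the bait.
    Neighbors within ``window`` (= 2f by default) can donate flank
    coverage.
    """

    flank: int = 300
    window: int | None = None

    def __post_init__(self):
        if self.flank <= 0:
            raise ValueError("flank must be positive")
        if self.window is None:
            self.window = 2 * self.flank


@dataclass
class SmootherSpec:
    """Trend smoother for bias-ordered detrending.

    ``window_fraction`` sizes the window for the GC correction, whose
    trend is strongly nonlinear (unimodal); repeat and density trends are
    close to monotone-linear, so their corrections widen the window by
    ``linear_window_factor`` to cut estimator variance without losing the
    trend.
    """

    method: str = "rolling_median"
    window_fraction: float = 0.1
    min_window: int = 50
    linear_window_factor: float = 3.0
    monotone: bool = False

    def __post_init__(self):
        if self.method not in ("rolling_median", "lowess", "kaiser"):
            raise ValueError(f"unknown smoother {self.method!r}")
        if not 0 < self.window_fraction <= 1:
            raise ValueError("window_fraction must be in (0, 1]")
        if self.linear_window_factor < 1:
            raise ValueError("linear_window_factor must be >= 1")

    def widened(self) -> "SmootherSpec":
        """Variant for covariates whose trend is monotone (repeat fraction,
        target density): wider window plus an isotonic constraint on the
        fitted trend, since the model guarantees the bias is a monotone
        function of the covariate."""
        from dataclasses import replace

        return replace(
            self,
            window_fraction=min(1.0, self.window_fraction * self.linear_window_factor),
            monotone=True,
        )


# ---------------------------------------------------------------------------
# target-density model


def _profile_integral(a: float, b: float, c: float, d: float, f: float) -> float:
    """Exact integral over [a, b) of the capture-efficiency profile of a
    bait [c, d): linear ramps of half-width f at each edge (zero at f
    outside, full at f inside), clipped to [0, 1]."""

    def phi(x: float) -> float:
        return max(0.0, min(1.0, (x - (c - f)) / (2 * f), ((d + f) - x) / (2 * f)))

    lo, hi = max(a, c - f), min(b, d + f)
    if hi <= lo:
        return 0.0
    breaks = (c - f, c + f, d - f, d + f, (c + d) / 2.0)  # incl. ramp crossing
    knots = sorted({lo, hi, *(k for k in breaks if lo < k < hi)})
    total = 0.0
    for x0, x1 in zip(knots[:-1], knots[1:]):
        total += 0.5 * (phi(x0) + phi(x1)) * (x1 - x0)  # exact: phi piecewise linear
    return total


def density_bias(
    bin_start: int,
    bin_end: int,
    neighbors: list[tuple[int, int]],
    params: DensityParams | None = None,
) -> float:
    """Edge-effect 'density' statistic for one on-target bin.

    Returns gain minus loss: the expected fractional depth contributed by
    the bin's own ramped profile plus overlapping flanks of neighbors,
    relative to a bait with no edge effects.  Negative for isolated bins
    (more negative the smaller the bin), increasing toward zero with size,
    and strictly increased by close neighbors — a monotone proxy for the
    true read-depth bias, which is all the rolling-median correction needs.
    """
    params = params or DensityParams()
    s = bin_end - bin_start
    if s <= 0:
        raise ValueError("non-positive bin length")
    f = float(params.flank)
    total = _profile_integral(bin_start, bin_end, bin_start, bin_end, f)
    for c, d in neighbors:
        if c == bin_start and d == bin_end:
            continue
        if d + f <= bin_start or c - f >= bin_end:
            continue
        total += _profile_integral(bin_start, bin_end, c, d, f)
    return total / s - 1.0


def density_values(bins: BinTable, params: DensityParams | None = None) -> np.ndarray:
    """Density statistic for every bin, using same-chromosome neighbors
    within the search window."""
    params = params or DensityParams()
    out = np.empty(len(bins))
    df = bins.data
    for chrom, sub in df.groupby("chromosome", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        idx = sub.index.to_numpy()
        for k, (s, e) in enumerate(zip(starts, ends)):
            lo = np.searchsorted(ends, s - params.window, side="right")
            hi = np.searchsorted(starts, e + params.window, side="left")
            neigh = [
                (int(starts[j]), int(ends[j])) for j in range(lo, hi) if j != k
            ]
            out[idx[k]] = density_bias(int(s), int(e), neigh, params)
    return out


# ---------------------------------------------------------------------------
# trend estimation and subtraction


def _window_size(n: int, spec: SmootherSpec) -> int:
    return min(n, max(spec.min_window, int(round(spec.window_fraction * n))))


def _trend_in_order(values: np.ndarray, bias: np.ndarray, spec: SmootherSpec) -> np.ndarray:
    """Trend of ``values`` as a function of ``bias``, evaluated per point."""
    n = len(values)
    window = _window_size(n, spec)
    order = np.lexsort((np.arange(n), bias))  # stable under ties
    if window >= n or n < 3:
        return np.full(n, float(np.median(values)))
    if spec.method == "lowess":
        fitted = sm_lowess(
            values[order], bias[order], frac=window / n, return_sorted=False
        )
        trend_sorted = fitted
    elif spec.method == "kaiser":
        kernel = np.kaiser(window, 14.0)
        v = values[order]
        num = np.convolve(v, kernel, mode="same")
        den = np.convolve(np.ones(n), kernel, mode="same")
        trend_sorted = num / den
    else:  # rolling median, centered, edges by symmetric window shrinkage
        trend_sorted = _rolling_median_symmetric(values[order], window)
    if spec.monotone:
        trend_sorted = _monotone_projection(trend_sorted)
    trend = np.empty(n)
    trend[order] = trend_sorted
    return trend


def _monotone_projection(trend: np.ndarray) -> np.ndarray:
    """Project a fitted trend onto monotone functions (direction chosen by
    fit quality), removing non-monotone wander of the estimate."""
    from scipy.optimize import isotonic_regression

    inc = isotonic_regression(trend, increasing=True).x
    dec = isotonic_regression(trend, increasing=False).x
    if np.sum((trend - inc) ** 2) <= np.sum((trend - dec) ** 2):
        return inc
    return dec


def _rolling_median_symmetric(v: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling median with symmetric shrinking windows at the edges
    (position i uses [i-k, i+k], k = min(h, i, n-1-i)).  Symmetric windows
    make the median track a monotone sequence exactly, so detrending a
    noiseless monotone trend leaves an exactly flat residual."""
    n = len(v)
    h = max(1, window // 2)
    out = np.empty(n)
    if n >= 2 * h + 1:
        interior = (
            pd.Series(v).rolling(2 * h + 1, center=True).median().to_numpy()
        )
        out[h : n - h] = interior[h : n - h]
    for i in range(min(h, n)):
        out[i] = np.median(v[: 2 * i + 1])
    for i in range(max(n - h, 0), n):
        k = n - 1 - i
        out[i] = np.median(v[i - k :])
    return out


def rolling_median_correct(
    values: np.ndarray, bias: np.ndarray, spec: SmootherSpec | None = None
) -> np.ndarray:
    """Subtract the bias-ordered rolling trend from log2 values.

    Bins are sorted by the covariate, a rolling median (or the configured
    smoother) of the values in that order estimates the expected bias, and
    that midpoint value is subtracted from each bin; output is returned in
    the original bin order.  A constant covariate degenerates to global
    median centering.
    """
    spec = spec or SmootherSpec()
    values = np.asarray(values, dtype=float)
    bias = np.asarray(bias, dtype=float)
    if values.shape != bias.shape:
        raise ValueError("values and bias must align")
    if len(values) == 0:
        return values.copy()
    if np.all(bias == bias[0]):
        return values - float(np.median(values))
    return values - _trend_in_order(values, bias, spec)


# ---------------------------------------------------------------------------
# whole-sample correction


def correct_table(
    sample: BinTable,
    spec: SmootherSpec | None = None,
    density: DensityParams | None = None,
) -> BinTable:
    """Apply GC, repeat and density corrections to a combined coverage table.

    The table must carry ``gc`` and ``rmask`` columns (normally copied from
    the reference profile).  Corrections are applied in the order
    GC -> repeat/density, each within its scope (see module docstring).
    """
    spec = spec or SmootherSpec()
    density = density or DensityParams()
    for col in ("gc", "rmask"):
        if col not in sample.data.columns:
            raise TableError(f"missing covariate column {col!r}")
    out = sample.copy()
    log2 = out.log2.copy()
    on = out.on_target_mask()
    off = ~on

    for mask in (on, off):  # GC on both sets, independently
        if mask.sum() >= 2:
            log2[mask] = rolling_median_correct(
                log2[mask], out.data["gc"].to_numpy(dtype=float)[mask], spec
            )
    wide = spec.widened()  # near-linear trends: wider window, less noise
    if off.sum() >= 2:  # repeats: off-target only
        log2[off] = rolling_median_correct(
            log2[off], out.data["rmask"].to_numpy(dtype=float)[off], wide
        )
    if on.sum() >= 2:  # density: on-target only
        on_bins = BinTable(out.data.loc[on], role="target", validate=False)
        dens = density_values(on_bins, density)
        log2[on] = rolling_median_correct(log2[on], dens, wide)
    out.data["log2"] = log2
    return out


def correct_sample(
    on: BinTable,
    off: BinTable,
    profile: BinTable,
    spec: SmootherSpec | None = None,
    density: DensityParams | None = None,
) -> tuple[BinTable, BinTable]:
    """Bias-correct a sample's on- and off-target coverage tables using the
    covariates stored in the reference profile; bin count and order are
    preserved, only log2 changes."""
    combined = BinTable(
        pd.concat([on.data, off.data], ignore_index=True),
        role="coverage",
        sample_id=on.sample_id,
    )
    cov = profile.data.set_index(["chromosome", "start", "end"])
    idx = pd.MultiIndex.from_arrays(
        [combined.chromosome, combined.start, combined.end]
    )
    try:
        combined.data["gc"] = cov["gc"].reindex(idx).to_numpy()
        combined.data["rmask"] = cov["rmask"].reindex(idx).to_numpy()
    except KeyError as exc:
        raise TableError(f"missing covariate column {exc}") from None
    if combined.data["gc"].isna().any():
        bad = combined.data[combined.data["gc"].isna()].iloc[0]
        raise TableError(
            f"bin {bad['chromosome']}:{bad['start']}-{bad['end']} absent from reference"
        )
    fixed = correct_table(combined, spec, density)
    on_mask = fixed.on_target_mask()
    keep = ["chromosome", "start", "end", "gene", "log2"] + (
        ["depth"] if "depth" in fixed.data.columns else []
    )
    on_out = BinTable(fixed.data.loc[on_mask, keep], role="coverage", sample_id=on.sample_id)
    off_out = BinTable(fixed.data.loc[~on_mask, keep], role="coverage", sample_id=off.sample_id)
    return on_out, off_out
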