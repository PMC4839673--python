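"""The "fix" stage: reference normalization of a test sample.

Combines a sample's on- and off-target binned read depths, drops bins the
reference flags as unreliable, removes systematic biases, subtracts the
reference log2 depth, median-centers the resulting copy ratios, and weights
each bin for segmentation.  Finally the more variable of the on-/off-target
sets is down-weighted in proportion so neither dominates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .bias import DensityParams, SmootherSpec, correct_table
from .tables import ANTITARGET_LABEL, BinTable, TableError

logger = logging.getLogger(__name__)


def bin_weights(df: pd.DataFrame, n_controls: int) -> np.ndarray:
    """Per-bin weights in (0, 1] from three multiplicative factors.

    * w_size — min(1, bin length / median length within its on/off set):
      larger bins average depth over more bases.
    * w_center — 2^(-|reference log2|): bins whose expected depth deviates
      from the global median are less trustworthy.  Needs >= 1 control.
    * w_spread — 1 / (1 + (spread / 0.25)^2): bins with erratic coverage
      across the control pool are de-emphasized.  Needs > 1 control.
    """
    lengths = (df["end"] - df["start"]).to_numpy(dtype=float)
    on = (df["gene"] != ANTITARGET_LABEL).to_numpy()
    w = np.ones(len(df))
    for mask in (on, ~on):
        if mask.any():
            w[mask] = np.minimum(1.0, lengths[mask] / np.median(lengths[mask]))
    if n_controls >= 1 and "ref_log2" in df.columns:
        w *= 2.0 ** (-np.abs(df["ref_log2"].to_numpy(dtype=float)))
    if n_controls > 1 and "spread" in df.columns:
        spread = df["spread"].to_numpy(dtype=float)
        if (spread[np.isfinite(spread)] < 0).any():
            raise TableError("negative spread in reference profile")
        with np.errstate(divide="ignore"):
            w_spread = 1.0 / (1.0 + (spread / 0.25) ** 2)
        w *= np.where(np.isfinite(spread), w_spread, 0.0)
    return w


def _diff_variability(log2: np.ndarray) -> float:
    """Robust variability: scaled MAD of successive differences of the
    genomically ordered log2 values (insensitive to true CNV steps)."""
    if len(log2) < 3:
        return 0.0
    d = np.diff(log2)
    return float(stats.median_abs_deviation(d, scale="normal") / np.sqrt(2))


def balance_on_off(ratio: BinTable) -> BinTable:
    """Down-weight the more variable of the on-/off-target bin sets by the
    ratio of the two variabilities; a missing set is a no-op."""
    out = ratio.copy()
    on = out.on_target_mask()
    if not on.any() or on.all():
        logger.warning("only one of the on/off-target sets present; weights unchanged")
        return out
    v_on = _diff_variability(out.log2[on])
    v_off = _diff_variability(out.log2[~on])
    if v_on <= 0 or v_off <= 0 or v_on == v_off:
        return out
    w = out.data["weight"].to_numpy(dtype=float)
    if v_on > v_off:
        w[on] *= v_off / v_on
    else:
        w[~on] *= v_on / v_off
    out.data["weight"] = w
    return out


def normalize_sample(
    on: BinTable,
    off: BinTable,
    profile: BinTable,
    spec: SmootherSpec | None = None,
    density: DensityParams | None = None,
    n_controls: int | None = None,
) -> BinTable:
    """Turn raw on/off-target coverages into weighted log2 copy ratios.

    Steps: merge the two coverage tables; drop bins flagged in the
    reference (sentinel spread); apply GC/repeat/density corrections using
    the reference covariates; subtract the reference log2; median-center;
    attach bin weights and balance the two bin sets.
    """
    if n_controls is None:
        n_controls = profile.n_controls if profile.n_controls is not None else 1
    merged = pd.concat([on.data, off.data], ignore_index=True)
    sample = BinTable(merged, role="coverage", sample_id=on.sample_id or off.sample_id)

    ref = profile.data.set_index(["chromosome", "start", "end"])
    idx = pd.MultiIndex.from_arrays([sample.chromosome, sample.start, sample.end])
    aligned = ref.reindex(idx)
    if aligned["log2"].isna().any():
        miss = idx[aligned["log2"].isna().to_numpy()][0]
        raise TableError(f"bin {miss} not present in the reference profile")
    for col in ("gc", "rmask"):
        if col not in aligned.columns:
            raise TableError(f"reference profile lacks covariate {col!r}")
        sample.data[col] = aligned[col].to_numpy()
    sample.data["ref_log2"] = aligned["log2"].to_numpy(dtype=float)
    sample.data["spread"] = (
        aligned["spread"].to_numpy(dtype=float)
        if "spread" in aligned.columns
        else np.zeros(len(sample))
    )

    flagged = ~np.isfinite(sample.data["spread"].to_numpy(dtype=float))
    covar_missing = sample.data[["gc", "rmask"]].isna().any(axis=1).to_numpy()
    drop = flagged | covar_missing
    if drop.any():
        logger.info("dropping %d/%d bins flagged by the reference", drop.sum(), len(sample))
    if drop.all():
        raise TableError("all bins dropped by reference criteria")
    if drop.sum() > 0.5 * len(sample):
        logger.warning("more than half of all bins dropped by reference criteria")
    kept = BinTable(sample.data.loc[~drop], role="coverage", sample_id=sample.sample_id)

    corrected = correct_table(kept, spec, density)
    df = corrected.data
    df["log2"] = df["log2"].to_numpy(dtype=float) - df["ref_log2"].to_numpy(dtype=float)
    df["weight"] = bin_weights(df, n_controls)
    keep_cols = ["chromosome", "start", "end", "gene", "log2", "weight"]
    ratio = BinTable(df[keep_cols], role="ratio", sample_id=sample.sample_id)
    ratio = ratio.median_center(autosomes_only=True)
    return balance_on_off(ratio)
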