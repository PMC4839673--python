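"""Panel-of-normals reference: expected depth, spread, GC and repeat content.

The reference profile stores, per bin, the expected (bias-corrected,
averaged) log2 read depth across control samples, the dispersion ("spread")
of the controls at that bin, and the sequence covariates (GC fraction,
repeat-masked fraction) used for bias correction.  With no controls a flat
reference of zeros can be used; a "male reference" stores the X chromosome
at half the autosomal expectation (log2 -1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyfaidx import Fasta
from scipy import stats

from .bias import DensityParams, SmootherSpec, correct_table
from .tables import SEX_CHROMS, BinTable, SPREAD_SENTINEL, TableError

_GC_CHARS = set("GCgc")
_N_CHARS = set("Nn")


def _scaled_mad(a: np.ndarray, axis=0) -> np.ndarray:
    return stats.median_abs_deviation(a, axis=axis, scale="normal")


def _iqr(a: np.ndarray, axis=0) -> np.ndarray:
    return np.percentile(a, 75, axis=axis) - np.percentile(a, 25, axis=axis)


#: registry of per-bin dispersion statistics for the control pool
SPREAD_STATS = {
    "mad": _scaled_mad,
    "std": lambda a, axis=0: np.std(a, axis=axis, ddof=1),
    "iqr": _iqr,
}


@dataclass
class ReferenceParams:
    male_reference: bool = False
    controls_are_male: bool = False
    min_control_depth: float = 0.05
    spread_stat: str = "mad"
    smoother: SmootherSpec = field(default_factory=SmootherSpec)
    density: DensityParams = field(default_factory=DensityParams)
    sex_chroms: frozenset = SEX_CHROMS

    def __post_init__(self):
        if self.spread_stat not in SPREAD_STATS:
            raise ValueError(
                f"unknown spread statistic {self.spread_stat!r}; "
                f"choose from {sorted(SPREAD_STATS)}"
            )


def annotate_gc_rmask(bins: BinTable, fasta_path) -> BinTable:
    """Attach GC fraction and repeat-masked (soft-masked lowercase) fraction.

    GC is computed over non-N bases; an all-N bin records the neutral value
    0.5.  Lowercase bases follow the UCSC RepeatMasker soft-masking
    convention.
    """
    genome = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=False)
    gcs = np.empty(len(bins))
    rmasks = np.empty(len(bins))
    for i, (chrom, s, e) in enumerate(zip(bins.chromosome, bins.start, bins.end)):
        if chrom not in genome:
            raise TableError(f"chromosome {chrom} absent from {fasta_path}")
        if e > len(genome[chrom]):
            raise TableError(f"bin {chrom}:{s}-{e} extends beyond sequence end")
        seq = genome[chrom][int(s):int(e)]
        n_gc = sum(1 for c in seq if c in _GC_CHARS)
        n_n = sum(1 for c in seq if c in _N_CHARS)
        informative = len(seq) - n_n
        gcs[i] = n_gc / informative if informative else 0.5
        rmasks[i] = sum(1 for c in seq if c.islower()) / len(seq)
    out = bins.copy()
    out.data["gc"] = gcs
    out.data["rmask"] = rmasks
    return out


def _chrx_shift(params: ReferenceParams) -> float:
    """Shift applied to control X-bin log2 so the stored expectation matches
    the declared reference sex.

    A male reference expects X at half the autosomal depth (log2 -1).  If
    the controls' X ploidy already matches the declared reference sex, no
    shift is needed.
    """
    target = -1.0 if params.male_reference else 0.0
    observed = -1.0 if params.controls_are_male else 0.0
    return target - observed


def flat_reference(bins: BinTable, male_reference: bool = False) -> BinTable:
    """A 'generic' reference: expected log2 0 and spread 0 at every bin.

    With male_reference, X-chromosome bins expect log2 -1 (one copy of X
    against a diploid autosomal baseline).
    """
    if len(bins) == 0:
        raise TableError("empty bin set")
    out = bins.copy()
    out.role = "reference"
    log2 = np.zeros(len(bins))
    if male_reference:
        is_x = out.data["chromosome"].isin(["X", "chrX"]).to_numpy()
        log2[is_x] = -1.0
    out.data["log2"] = log2
    out.data["spread"] = np.zeros(len(bins))
    if "gc" not in out.data.columns:
        out.data["gc"] = np.nan
    if "rmask" not in out.data.columns:
        out.data["rmask"] = np.nan
    out.n_controls = 0
    return out


def build_reference(
    controls: list[tuple[BinTable, BinTable]],
    bins: BinTable,
    params: ReferenceParams | None = None,
) -> BinTable:
    """Pool control samples into an expected-depth profile.

    Each control's on- and off-target coverages are combined, bias-corrected
    against the bin covariates, then averaged per bin; the spread statistic
    across controls flags erratic bins.  Bins where at least half the
    controls fall below ``min_control_depth`` reads/base keep their row but
    get a sentinel (infinite) spread so normalization drops them and bin
    sets stay aligned.

    ``bins`` must carry gc/rmask annotations (see annotate_gc_rmask) and
    defines the reference bin set; every control must match it exactly.
    """
    params = params or ReferenceParams()
    if "gc" not in bins.data.columns or "rmask" not in bins.data.columns:
        raise TableError("bins must be annotated with gc/rmask before building a reference")
    if not controls:
        ref = bins.copy()
        ref.role = "reference"
        flat = flat_reference(bins, params.male_reference)
        ref.data["log2"] = flat.data["log2"].to_numpy()
        ref.data["spread"] = 0.0
        ref.n_controls = 0
        return ref

    coords = list(zip(bins.chromosome, bins.start, bins.end))
    corrected = []
    depths = []
    for on, off in controls:
        combined = pd.concat([on.data, off.data], ignore_index=True)
        sample = BinTable(combined, role="coverage", sample_id=on.sample_id)
        if list(zip(sample.chromosome, sample.start, sample.end)) != coords:
            own = set(zip(sample.chromosome, sample.start, sample.end))
            diverge = next((c for c in coords if c not in own), None)
            raise TableError(f"control bin set mismatch; first divergent bin: {diverge}")
        sample.data["gc"] = bins.data["gc"].to_numpy()
        sample.data["rmask"] = bins.data["rmask"].to_numpy()
        fixed = correct_table(sample, params.smoother, params.density)
        corrected.append(fixed.log2)
        if "depth" in sample.data.columns:
            depths.append(sample.data["depth"].to_numpy(dtype=float))

    mat = np.vstack(corrected)  # controls x bins
    shift = _chrx_shift(params)
    if shift:
        is_x = bins.data["chromosome"].isin(["X", "chrX"]).to_numpy()
        mat[:, is_x] += shift
    ref = bins.copy()
    ref.role = "reference"
    ref.data["log2"] = mat.mean(axis=0)
    if mat.shape[0] > 1:
        spread = SPREAD_STATS[params.spread_stat](mat, axis=0)
    else:
        spread = np.zeros(mat.shape[1])
    if depths:
        dmat = np.vstack(depths)
        low = (dmat < params.min_control_depth).sum(axis=0) >= np.ceil(dmat.shape[0] / 2)
        spread = np.where(low, SPREAD_SENTINEL, spread)
    ref.data["spread"] = spread
    ref.n_controls = len(controls)
    return ref
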