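"""Truth-annotated synthetic data: genomes, targets, coverages, tiny BAMs.

The generator emulates a hybrid-capture experiment on a small multi-
chromosome genome: exon-like targets grouped into genes, a smooth spatial
GC field, soft-masked repeat blocks in intergenic space, and per-bin read
depths produced from a known integer copy-number profile with injected
GC / target-density / repeat biases, a per-bin capture-efficiency effect
shared by all samples of a cohort, and multiplicative sampling noise.
Every quantity the pipeline estimates has an exact truth table to compare
against.

All generators are deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam

from . import bias, reference
from .binning import BinningParams, antitarget_bins, split_targets
from .coverage import DepthParams, depths_to_table
from .normalize import normalize_sample
from .tables import ANTITARGET_LABEL, BinTable


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a desk-scale hybrid-capture experiment: 2 chromosomes
    of 30 Mb, 150 genes of 5 exons (~1,500 on-target bins after
    subdivision, ~400 off-target bins of ~150 kb), 300x on-target and 2x
    off-target mean depth, biases of realistic log2 magnitude and 0.15
    log2 units of multiplicative noise.
    """

    n_chroms: int = 2
    chrom_length: int = 30_000_000
    n_genes: int = 150
    exons_per_gene: int = 5
    exon_size_mean: float = 450.0
    exon_size_sd: float = 150.0
    intron_size: int = 5_000
    gc_baseline: float = 0.45
    gc_amplitude: float = 0.12
    gc_wavelength: float = 7e6
    gc_jitter: float = 0.03
    repeat_density: float = 0.3
    repeat_block: int = 500
    purity: float = 1.0
    ploidy: int = 2
    mean_on_target_depth: float = 300.0
    mean_off_target_depth: float = 2.0
    bias_amplitudes: tuple[float, float, float] = (0.8, 1.2, 1.2)  # gc, density, repeat
    bin_effect_sd: float = 0.25
    noise_sd: float = 0.15
    read_length: int = 100
    binning: BinningParams = field(default_factory=BinningParams)
    seed: int = 0


def _chrom_names(config: SimConfig) -> list[str]:
    return [f"chr{i + 1}" for i in range(config.n_chroms)]


# ---------------------------------------------------------------------------
# genome layout


def gene_layout(config: SimConfig) -> pd.DataFrame:
    """Deterministic exon coordinates: genes evenly spaced with jitter."""
    rng = np.random.default_rng(config.seed)
    chroms = _chrom_names(config)
    per_chrom = int(np.ceil(config.n_genes / config.n_chroms))
    rows = []
    gene_no = 0
    for chrom in chroms:
        spacing = config.chrom_length / (per_chrom + 1)
        for g in range(per_chrom):
            if gene_no >= config.n_genes:
                break
            gstart = int((g + 0.5) * spacing + rng.uniform(0, 0.3 * spacing))
            name = f"GENE{gene_no + 1:04d}"
            pos = gstart
            for _ in range(config.exons_per_gene):
                size = int(
                    np.clip(
                        rng.normal(config.exon_size_mean, config.exon_size_sd),
                        150,
                        1200,
                    )
                )
                rows.append((chrom, pos, pos + size, name))
                pos += size + config.intron_size
            gene_no += 1
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "gene"])


def make_targets(config: SimConfig, path=None) -> pd.DataFrame:
    """Exon targets as a BED-style frame; optionally written as BED4."""
    targets = gene_layout(config)
    if path is not None:
        targets.to_csv(path, sep="\t", index=False, header=False, lineterminator="\n")
    return targets


def gc_at(config: SimConfig, chrom_index: np.ndarray, position: np.ndarray) -> np.ndarray:
    """The smooth spatial GC field (no jitter)."""
    phase = 2 * np.pi * np.asarray(chrom_index) / max(config.n_chroms, 1)
    wave = np.sin(2 * np.pi * np.asarray(position) / config.gc_wavelength + phase)
    return np.clip(config.gc_baseline + config.gc_amplitude * wave, 0.2, 0.8)


def make_genome(config: SimConfig, path) -> None:
    """Write a soft-masked FASTA realizing the GC field and repeat blocks.

    Intended for small configurations (tests, BAM round trips); the cohort
    simulation works from analytic bin annotations instead.
    """
    rng = np.random.default_rng(config.seed + 1)
    targets = gene_layout(config)
    bases = np.array(list("ACGT"))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for ci, chrom in enumerate(_chrom_names(config)):
            fh.write(f">{chrom}\n")
            pos = np.arange(config.chrom_length)
            gc = gc_at(config, np.full(len(pos), ci), pos)
            p_gc = gc / 2.0
            probs = np.stack([(1 - gc) / 2, p_gc, p_gc, (1 - gc) / 2], axis=1)
            draws = rng.random((config.chrom_length, 1))
            cum = np.cumsum(probs, axis=1)
            idx = (draws > cum[:, :-1]).sum(axis=1)
            seq = bases[idx]
            # lowercase repeat blocks in intergenic space
            tgt = targets[targets["chromosome"] == chrom]
            occupied = list(zip(tgt["start"], tgt["end"]))
            n_blocks = int(
                config.repeat_density * config.chrom_length / config.repeat_block
            )
            for _ in range(n_blocks):
                s = int(rng.integers(0, config.chrom_length - config.repeat_block))
                e = s + config.repeat_block
                if any(s < te and e > ts for ts, te in occupied):
                    continue
                seq[s:e] = np.char.lower(seq[s:e])
            text = "".join(seq)
            for i in range(0, len(text), 70):
                fh.write(text[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# bins and annotations


def make_bins(config: SimConfig) -> tuple[BinTable, BinTable]:
    """On-target and antitarget bins for the synthetic panel."""
    targets = gene_layout(config)
    lengths = {c: config.chrom_length for c in _chrom_names(config)}
    on = split_targets(targets, config.binning.avg_target_bin)
    off = antitarget_bins(targets, chrom_lengths=lengths, params=config.binning)
    return on, off


def annotate_synthetic(bins: BinTable, config: SimConfig) -> BinTable:
    """Attach analytic gc/rmask annotations (deterministic per bin).

    GC follows the spatial field plus a small per-bin jitter (GC is
    genuinely spatially smooth — isochores).  The repeat-masked fraction is
    ~0 on targets (exonic) and, on off-target bins, dominated by
    bin-to-bin variation around the genome-wide repeat density, as real
    per-bin RepeatMasker fractions are.
    """
    rng = np.random.default_rng(config.seed + 2)
    out = bins.copy()
    chrom_idx = out.data["chromosome"].map(
        {c: i for i, c in enumerate(_chrom_names(config))}
    ).to_numpy()
    mid = (out.start + out.end) / 2
    gc = gc_at(config, chrom_idx, mid) + rng.normal(0, config.gc_jitter, len(out))
    out.data["gc"] = np.clip(gc, 0.15, 0.85)
    on = out.on_target_mask()
    rmask = np.zeros(len(out))
    rmask_off = np.clip(
        config.repeat_density + rng.normal(0, 0.2, len(out)), 0.02, 0.9
    )
    rmask[~on] = rmask_off[~on]
    out.data["rmask"] = rmask
    return out


def cohort_bin_effect(bins: BinTable, config: SimConfig) -> np.ndarray:
    """Per-bin capture-efficiency log2 offset, shared across all samples of
    a cohort; only normalization to a pooled reference can remove it."""
    rng = np.random.default_rng(config.seed + 3)
    return rng.normal(0.0, config.bin_effect_sd, len(bins))


# ---------------------------------------------------------------------------
# copy-number profiles and coverage


def default_cn_profile(config: SimConfig, tumor_index: int) -> list[tuple[str, int, int, int]]:
    """A gain (cn 4) on chr1 and a loss (cn 1) on chr2 for each tumor, at
    positions drawn deterministically from the cohort seed."""
    rng = np.random.default_rng(config.seed + 1000 + tumor_index)
    events = []
    # ~20% of a chromosome, capped at 6 Mb (the default 30 Mb chromosomes)
    span = min(6_000_000, int(0.2 * config.chrom_length))
    chroms = _chrom_names(config)
    s1 = int(rng.uniform(0.1, 0.7) * config.chrom_length)
    events.append((chroms[0], s1, min(s1 + span, config.chrom_length), 4))
    if len(chroms) > 1:
        s2 = int(rng.uniform(0.1, 0.7) * config.chrom_length)
        events.append((chroms[1], s2, min(s2 + span, config.chrom_length), 1))
    return events


def _cn_per_bin(bins: BinTable, cn_profile, ploidy: int) -> np.ndarray:
    cn = np.full(len(bins), ploidy, dtype=float)
    if cn_profile:
        mid = (bins.start + bins.end) / 2
        for chrom, s, e, c in cn_profile:
            mask = (bins.chromosome == chrom).to_numpy() & (mid >= s) & (mid < e)
            cn[mask] = c
    return cn


def expected_log2(cn: np.ndarray, purity: float, ploidy: int) -> np.ndarray:
    """Truth log2 ratio of a mixture: purity * cn/ploidy + (1 - purity)."""
    r = purity * cn / ploidy + (1.0 - purity)
    return np.log2(np.maximum(r, 2.0**-10))


def bias_terms(bins_annotated: BinTable, config: SimConfig) -> np.ndarray:
    """Injected per-bin log2 bias: sigmoid GC trend on all bins, the
    edge-geometry density statistic on targets, and a linear repeat term on
    repeat-masked (off-target) bins."""
    amp_gc, amp_density, amp_repeat = config.bias_amplitudes
    gc = bins_annotated.data["gc"].to_numpy(dtype=float)
    term = amp_gc * (1.0 / (1.0 + np.exp(-(gc - 0.45) / 0.05)) - 0.5)
    on = bins_annotated.on_target_mask()
    if amp_density and on.any():
        on_bins = BinTable(bins_annotated.data.loc[on], role="target", validate=False)
        term[on] += amp_density * bias.density_values(on_bins)
    if amp_repeat:
        rmask = bins_annotated.data["rmask"].to_numpy(dtype=float)
        term += -amp_repeat * rmask
    return term


def simulate_coverage(
    bins_annotated: BinTable,
    config: SimConfig,
    rng: np.random.Generator,
    cn_profile: list[tuple[str, int, int, int]] | None = None,
    purity: float | None = None,
    bin_effect: np.ndarray | None = None,
    sample_id: str | None = None,
) -> tuple[BinTable, BinTable, BinTable]:
    """Draw one sample's (on, off) coverage tables plus its exact truth.

    Expected linear depth per bin is
    ``base_depth * (purity*cn/ploidy + 1-purity) * 2^(biases + bin_effect)``
    with multiplicative log-normal noise of sd ``noise_sd`` log2 units.
    The truth table stores the integer cn and expected log2 ratio per bin.
    """
    purity = config.purity if purity is None else purity
    on = bins_annotated.on_target_mask()
    base = np.where(on, config.mean_on_target_depth, config.mean_off_target_depth)
    cn = _cn_per_bin(bins_annotated, cn_profile, config.ploidy)
    truth_log2 = expected_log2(cn, purity, config.ploidy)
    log2_mean = np.log2(base) + truth_log2 + bias_terms(bins_annotated, config)
    if bin_effect is not None:
        log2_mean = log2_mean + bin_effect
    depths = 2.0 ** (log2_mean + rng.normal(0.0, config.noise_sd, len(bins_annotated)))

    params = DepthParams()
    on_bins = BinTable(bins_annotated.data.loc[on], role="target", validate=False)
    off_bins = BinTable(bins_annotated.data.loc[~on], role="target", validate=False)
    on_cov = depths_to_table(on_bins, depths[on], params, sample_id)
    off_cov = depths_to_table(off_bins, depths[~on], params, sample_id)

    truth = bins_annotated.copy()
    truth.data["cn"] = cn.astype(int)
    truth.data["log2"] = truth_log2
    return on_cov, off_cov, truth


@dataclass
class Cohort:
    config: SimConfig
    bins: BinTable  # annotated, on+off combined
    controls: list[tuple[BinTable, BinTable]]
    tumors: list[tuple[BinTable, BinTable]]
    truths: list[BinTable]  # per tumor
    bin_effect: np.ndarray


def simulate_cohort(
    config: SimConfig | None = None, n_controls: int = 4, n_tumors: int = 4
) -> Cohort:
    """The default desk-scale cohort: pooled controls plus tumors carrying
    known gains/losses, all sharing one panel and one bin-effect field."""
    config = config or SimConfig()
    on, off = make_bins(config)
    combined = BinTable(
        pd.concat([on.data, off.data], ignore_index=True), role="target"
    )
    annotated = annotate_synthetic(combined, config)
    eff = cohort_bin_effect(annotated, config)
    controls, tumors, truths = [], [], []
    for k in range(n_controls):
        rng = np.random.default_rng(config.seed + 10 + k)
        c_on, c_off, _ = simulate_coverage(
            annotated, config, rng, cn_profile=None, purity=1.0,
            bin_effect=eff, sample_id=f"normal_{k + 1}",
        )
        controls.append((c_on, c_off))
    for k in range(n_tumors):
        rng = np.random.default_rng(config.seed + 100 + k)
        profile = default_cn_profile(config, k)
        t_on, t_off, truth = simulate_coverage(
            annotated, config, rng, cn_profile=profile,
            bin_effect=eff, sample_id=f"tumor_{k + 1}",
        )
        tumors.append((t_on, t_off))
        truths.append(truth)
    return Cohort(config, annotated, controls, tumors, truths, eff)


# ---------------------------------------------------------------------------
# BAM realization


def simulate_bam(
    bins: BinTable,
    config: SimConfig,
    path,
    rng: np.random.Generator,
    depths: np.ndarray | None = None,
    duplicate_rate: float = 0.0,
) -> None:
    """Write a sorted, indexed BAM realizing per-bin depths within Poisson
    error.  Single-end read_length-bp reads are placed uniformly inside
    each bin; with ``duplicate_rate`` d, flagged duplicate copies are added
    so filtered/unfiltered depth differs by the factor 1/(1-d)."""
    L = config.read_length
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": c, "LN": config.chrom_length} for c in _chrom_names(config)
        ],
    }
    if depths is None:
        on = bins.on_target_mask()
        depths = np.where(on, config.mean_on_target_depth, config.mean_off_target_depth)
    reads: dict[str, list[tuple[int, bool]]] = {c: [] for c in _chrom_names(config)}
    for (chrom, s, e), depth in zip(
        zip(bins.chromosome, bins.start, bins.end), depths
    ):
        span = max(1, e - s - L)
        n = rng.poisson(depth * (e - s) / L)
        for start in rng.integers(s, s + span, size=n):
            reads[chrom].append((int(start), False))
            if duplicate_rate > 0 and rng.random() < duplicate_rate / (1 - duplicate_rate):
                reads[chrom].append((int(start), True))
    tmp_path = str(path)
    with pysam.AlignmentFile(tmp_path, "wb", header=header) as bam:
        i = 0
        for tid, chrom in enumerate(_chrom_names(config)):
            for start, is_dup in sorted(reads[chrom]):
                a = pysam.AlignedSegment()
                a.query_name = f"r{i:07d}"
                a.reference_id = tid
                a.reference_start = start
                a.mapping_quality = 60
                a.cigarstring = f"{L}M"
                a.query_sequence = "A" * L
                a.query_qualities = pysam.qualitystring_to_array("I" * L)
                a.flag = 0x400 if is_dup else 0
                bam.write(a)
                i += 1
    pysam.index(tmp_path)


# ---------------------------------------------------------------------------
# step-wise evaluation (bias-correction ladder)


def evaluate_steps(cohort: Cohort) -> pd.DataFrame:
    """Absolute deviation of bin log2 from truth at each correction step.

    Steps: raw median-centered depth; + GC correction; + density (target)
    and repeat (off-target) corrections; + normalization to the pooled
    reference.  Reports median and IQR of |log2 - truth| per tumor and bin
    set — the ladder used to judge what each correction buys.
    """
    spec = bias.SmootherSpec()
    dens = bias.DensityParams()
    ref_params = reference.ReferenceParams(smoother=spec, density=dens)
    profile = reference.build_reference(cohort.controls, cohort.bins, ref_params)

    ann = cohort.bins
    gc = ann.data["gc"].to_numpy(dtype=float)
    rmask = ann.data["rmask"].to_numpy(dtype=float)
    on = ann.on_target_mask()
    on_dens = bias.density_values(
        BinTable(ann.data.loc[on], role="target", validate=False), dens
    )

    rows = []
    for k, ((t_on, t_off), truth) in enumerate(zip(cohort.tumors, cohort.truths)):
        sample = BinTable(
            pd.concat([t_on.data, t_off.data], ignore_index=True),
            role="coverage",
            sample_id=t_on.sample_id,
        ).median_center()
        truth_log2 = truth.log2

        est = {}
        raw = sample.log2.copy()
        est["raw"] = raw
        after_gc = raw.copy()
        for mask in (on, ~on):
            after_gc[mask] = bias.rolling_median_correct(raw[mask], gc[mask], spec)
        est["gc"] = after_gc
        after_dr = after_gc.copy()
        wide = spec.widened()
        after_dr[~on] = bias.rolling_median_correct(after_gc[~on], rmask[~on], wide)
        after_dr[on] = bias.rolling_median_correct(after_gc[on], on_dens, wide)
        est["density_repeat"] = after_dr
        ratio = normalize_sample(t_on, t_off, profile, spec, dens)
        final = np.full(len(ann), np.nan)
        ref_idx = {
            key: i
            for i, key in enumerate(zip(ann.chromosome, ann.start, ann.end))
        }
        for key, val in zip(
            zip(ratio.chromosome, ratio.start, ratio.end), ratio.log2
        ):
            final[ref_idx[key]] = val
        est["reference"] = final

        for step, values in est.items():
            diff = values - truth_log2
            for set_name, mask in (("target", on), ("antitarget", ~on)):
                d = diff[mask]
                d = d[~np.isnan(d)]
                # deviation around the set median: a dispersion measure,
                # insensitive to the per-set level (which centering fixes)
                d = np.abs(d - np.median(d))
                rows.append(
                    {
                        "sample": t_on.sample_id or f"tumor_{k + 1}",
                        "step": step,
                        "bin_set": set_name,
                        "median_abs_dev": float(np.median(d)),
                        "iqr_abs_dev": float(
                            np.percentile(d, 75) - np.percentile(d, 25)
                        ),
                        "n": int(len(d)),
                    }
                )
    return pd.DataFrame(rows)


STEP_ORDER = ["raw", "gc", "density_repeat", "reference"]
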