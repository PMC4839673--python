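import numpy as np
import pandas as pd
import pysam
import pytest

from hybridcn.simulate import SimConfig, simulate_cohort
from hybridcn.tables import BinTable


@pytest.fixture(scope="session")
def default_cohort():
    """The default desk-scale synthetic cohort (4 controls + 4 tumors)."""
    return simulate_cohort(SimConfig(seed=0))


@pytest.fixture
def tiny_config():
    """A miniature genome small enough to write FASTA/BAM in tests."""
    return SimConfig(
        n_chroms=2,
        chrom_length=120_000,
        n_genes=6,
        exons_per_gene=2,
        intron_size=1_000,
        seed=0,
    )


def make_ratio(values, chrom="chr1", weights=None, gene="G", start0=0):
    """A ratio BinTable over consecutive 1 kb bins."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    df = pd.DataFrame(
        {
            "chromosome": chrom,
            "start": start0 + np.arange(n) * 1000,
            "end": start0 + np.arange(1, n + 1) * 1000,
            "gene": gene,
            "log2": values,
            "weight": 1.0 if weights is None else np.asarray(weights, dtype=float),
        }
    )
    return BinTable(df, role="ratio")


def write_bam(path, reads, chrom_lengths):
    """Write a sorted+indexed BAM from (chrom, start, cigar, flag, mapq) tuples."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in chrom_lengths.items()],
    }
    order = {c: i for i, c in enumerate(chrom_lengths)}
    reads = sorted(reads, key=lambda r: (order[r[0]], r[1]))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for i, (chrom, start, cigar, flag, mapq) in enumerate(reads):
            a = pysam.AlignedSegment()
            a.query_name = f"r{i}"
            a.reference_id = order[chrom]
            a.reference_start = start
            a.cigarstring = cigar
            a.flag = flag
            a.mapping_quality = mapq
            length = sum(n for op, n in a.cigartuples if op in (0, 1, 4, 7, 8))
            a.query_sequence = "A" * length
            a.query_qualities = pysam.qualitystring_to_array("I" * length)
            bam.write(a)
    pysam.index(str(path))
    return str(path)


def naive_depth(bam_path, chrom, start, end, min_mapq=0, count_duplicates=False,
                count_secondary=False):
    """Brute-force per-base pileup: an independent oracle for bin_depths."""
    total = 0
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        for pos in range(start, end):
            for read in bam.fetch(chrom, pos, pos + 1):
                if read.is_unmapped or read.is_qcfail:
                    continue
                if read.is_secondary and not count_secondary:
                    continue
                if read.is_duplicate and not count_duplicates:
                    continue
                if read.mapping_quality < min_mapq:
                    continue
                if pos in read.get_reference_positions():
                    total += 1
    return total / (end - start)
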