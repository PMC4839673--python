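"""Purity rescaling, copy-number calling, and report generation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hybridcn.calling import (
    breaks,
    call_absolute,
    fish_to_log2,
    gainloss,
    recenter,
    rescale_purity,
    residual_metrics,
    segment_metrics,
)
from hybridcn.tables import ANTITARGET_LABEL, BinTable, SegmentTable, TableError

from conftest import make_ratio


def segs(rows):
    return SegmentTable(
        pd.DataFrame(rows, columns=["chromosome", "start", "end", "log2", "n_bins", "weight"])
    )


class TestRescalePurity:
    def test_purity_one_is_identity(self):
        s = segs([("chr1", 0, 1000, 0.7, 10, 10.0)])
        np.testing.assert_allclose(rescale_purity(s, 1.0).log2, [0.7])

    def test_half_purity_hand_example(self):
        # observed ratio 0.75 at 50% purity: tumor ratio (0.75-0.5)/0.5 = 0.5
        s = segs([("chr1", 0, 1000, np.log2(0.75), 10, 10.0)])
        assert rescale_purity(s, 0.5).log2[0] == pytest.approx(-1.0)

    def test_neutral_is_fixed_point_for_any_purity(self):
        s = segs([("chr1", 0, 1000, 0.0, 10, 10.0)])
        for p in (0.2, 0.5, 0.9):
            assert rescale_purity(s, p).log2[0] == pytest.approx(0.0)

    def test_purity_zero_rejected(self):
        with pytest.raises(ValueError):
            rescale_purity(segs([("chr1", 0, 1, 0.0, 1, 1.0)]), 0.0)

    @pytest.mark.parametrize("purity", [0.3, 0.6, 0.9])
    def test_mixture_roundtrip_recovers_integer_cn(self, purity):
        ploidy = 2
        rows = []
        for cn in range(9):
            r_obs = purity * cn / ploidy + (1 - purity)
            rows.append(("chr1", cn * 1000, (cn + 1) * 1000, np.log2(max(r_obs, 2**-10)), 5, 5.0))
        called = call_absolute(rescale_purity(segs(rows), purity, ploidy), ploidy)
        assert list(called.data["cn"]) == list(range(9))


class TestRecenter:
    def test_weighted_median_example(self):
        s = segs(
            [
                ("chr1", 0, 10, -1.0, 10, 10.0),
                ("chr1", 10, 20, 0.0, 80, 80.0),
                ("chr1", 20, 30, 1.0, 10, 10.0),
            ]
        )
        np.testing.assert_allclose(recenter(s, "median").log2, [-1.0, 0.0, 1.0])

    def test_uniform_offset_removed(self):
        s = segs([("chr1", i * 10, (i + 1) * 10, 0.3, 5, 5.0) for i in range(4)])
        np.testing.assert_allclose(recenter(s, "median").log2, 0.0)
        np.testing.assert_allclose(recenter(s, "mean").log2, 0.0, atol=1e-12)

    def test_mode_centers_dominant_component(self):
        rng = np.random.default_rng(0)
        rows = []
        pos = 0
        # trimodal mixture: dominant component at +0.4, minor at -0.6 and +1.4
        for center, k in ((-0.6, 8), (0.4, 40), (1.4, 8)):
            for v in rng.normal(center, 0.05, k):
                rows.append(("chr1", pos, pos + 10, v, 10, 10.0))
                pos += 10
        out = recenter(segs(rows), "mode")
        dominant = np.sort(out.log2)[8:48]
        assert np.median(dominant) == pytest.approx(0.0, abs=0.05)

    def test_unknown_method_rejected(self):
        with pytest.raises(TableError):
            recenter(segs([("chr1", 0, 1, 0.0, 1, 1.0)]), "midhinge")


class TestCallAbsolute:
    @pytest.mark.parametrize(
        "log2,ploidy,cn",
        [(0.0, 2, 2), (1.0, 2, 4), (-1.0, 2, 1), (np.log2(5 / 6), 6, 5)],
    )
    def test_rounding_mode(self, log2, ploidy, cn):
        out = call_absolute(segs([("chr1", 0, 10, log2, 1, 1.0)]), ploidy)
        assert out.data["cn"].iat[0] == cn

    def test_left_inverse_of_cn_to_log2(self):
        for ploidy in (2, 4):
            for cn in range(0, 9):
                log2 = np.log2(cn / ploidy) if cn else -5.0
                out = call_absolute(segs([("chr1", 0, 10, log2, 1, 1.0)]), ploidy)
                assert out.data["cn"].iat[0] == cn

    def test_threshold_mode(self):
        cuts = (-1.1, -0.4, 0.3, 0.7)
        cases = {-2.0: 0, -0.5: 1, 0.0: 2, 0.5: 3, 1.5: 4}
        for log2, cn in cases.items():
            out = call_absolute(segs([("chr1", 0, 10, log2, 1, 1.0)]), thresholds=cuts)
            assert out.data["cn"].iat[0] == cn

    def test_sex_chromosome_ploidy_override(self):
        s = segs([("chr1", 0, 10, 0.0, 1, 1.0), ("chrX", 0, 10, 0.0, 1, 1.0)])
        out = call_absolute(s, 2, sex_chrom_ploidy={"chrX": 1})
        by = out.data.set_index("chromosome")["cn"]
        assert by.loc["chr1"] == 2 and by.loc["chrX"] == 1


@pytest.fixture
def gene_ratio():
    # three genes of 4 bins each, then off-target bins
    frames = []
    for i, g in enumerate(["A", "B", "C"]):
        frames.append(make_ratio([0.0] * 4, gene=g, start0=i * 4000).data)
    frames.append(make_ratio([0.0] * 4, gene=ANTITARGET_LABEL, start0=12000).data)
    return BinTable(pd.concat(frames, ignore_index=True), role="ratio")


class TestReports:
    def test_gainloss_reports_genes_beyond_threshold(self, gene_ratio):
        seg = segs(
            [
                ("chr1", 0, 4000, 1.0, 4, 4.0),     # covers gene A: gain
                ("chr1", 4000, 8000, 0.0, 4, 4.0),  # gene B: neutral
                ("chr1", 8000, 16000, -0.8, 8, 8.0),  # gene C: loss
            ]
        )
        out = gainloss(gene_ratio, seg, threshold=0.58)
        assert set(out["gene"]) == {"A", "C"}
        assert dict(zip(out["gene"], out["direction"])) == {"A": "gain", "C": "loss"}

    def test_gene_split_across_segments_reported_per_overlap(self, gene_ratio):
        seg = segs(
            [("chr1", 0, 2000, 1.0, 2, 2.0), ("chr1", 2000, 16000, 0.9, 14, 14.0)]
        )
        out = gainloss(gene_ratio, seg, threshold=0.58)
        assert (out["gene"] == "A").sum() == 2  # A overlaps both segments

    def test_off_target_bins_excluded_from_gene_reports(self, gene_ratio):
        seg = segs([("chr1", 0, 16000, 1.0, 16, 16.0)])
        out = gainloss(gene_ratio, seg, threshold=0.58)
        assert ANTITARGET_LABEL not in set(out["gene"])

    def test_breaks_enumeration_matches_oracle(self, gene_ratio):
        # boundaries at 2000 (inside A), 4000 (edge A/B), 9000 (inside C)
        seg = segs(
            [
                ("chr1", 0, 2000, 0.0, 2, 2.0),
                ("chr1", 2000, 4000, 1.0, 2, 2.0),
                ("chr1", 4000, 9000, 0.0, 5, 5.0),
                ("chr1", 9000, 16000, -1.0, 7, 7.0),
            ]
        )
        out = breaks(gene_ratio, seg)
        got = set(zip(out["gene"], out["breakpoint"]))
        assert got == {("A", 2000), ("C", 9000)}

    def test_three_segments_crossing_one_gene_give_two_breaks(self):
        ratio = make_ratio([0.0] * 9, gene="G")
        seg = segs(
            [
                ("chr1", 0, 3000, 0.0, 3, 3.0),
                ("chr1", 3000, 6000, 1.0, 3, 3.0),
                ("chr1", 6000, 9000, 0.0, 3, 3.0),
            ]
        )
        assert len(breaks(ratio, seg)) == 2


class TestResidualMetrics:
    def test_zero_residuals_give_zero_stats(self):
        ratio = make_ratio(np.full(20, 0.4))
        seg = segs([("chr1", 0, 20_000, 0.4, 20, 20.0)])
        out = residual_metrics(ratio, seg)
        assert all(v == 0 for v in out.values())

    def test_unscaled_mad_of_simple_residuals(self):
        ratio = make_ratio([-1.0, 0.0, 1.0])
        seg = segs([("chr1", 0, 3000, 0.0, 3, 3.0)])
        assert residual_metrics(ratio, seg)["mad"] == 1.0

    def test_scaled_mad_estimates_noise_sd(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 0.2, 10_000)
        ratio = make_ratio(vals)
        seg = segs([("chr1", 0, 10_000_000, 0.0, 10_000, 10_000.0)])
        assert residual_metrics(ratio, seg)["spread"] == pytest.approx(0.2, abs=0.01)

    def test_per_segment_metrics(self):
        ratio = make_ratio(np.concatenate([np.zeros(10), np.ones(10)]))
        seg = segs(
            [("chr1", 0, 10_000, 0.0, 10, 10.0), ("chr1", 10_000, 20_000, 1.0, 10, 10.0)]
        )
        out = segment_metrics(ratio, seg)
        assert len(out) == 2
        np.testing.assert_allclose(out["mad"], 0.0)

    def test_report_stable_under_bin_permutation(self, gene_ratio):
        seg = segs([("chr1", 0, 16000, 1.0, 16, 16.0)])
        shuffled = BinTable(
            gene_ratio.data.sample(frac=1, random_state=0), role="ratio"
        )
        a = gainloss(gene_ratio, seg, 0.5)
        b = gainloss(shuffled, seg, 0.5)
        pd.testing.assert_frame_equal(a, b)


@pytest.mark.parametrize("count,ploidy,expect", [(6, 6, 0.0), (12, 6, 1.0), (3, 6, -1.0)])
def test_fish_count_to_log2(count, ploidy, expect):
    assert fish_to_log2(count, ploidy) == expect
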