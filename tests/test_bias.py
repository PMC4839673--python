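"""Density geometry, rolling-median detrending, and correction scope rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hybridcn.bias import (
    DensityParams,
    SmootherSpec,
    correct_sample,
    correct_table,
    density_bias,
    density_values,
    rolling_median_correct,
)
from hybridcn.tables import ANTITARGET_LABEL, BinTable, TableError


class TestDensityBias:
    def test_isolated_huge_bin_approaches_zero(self):
        d = density_bias(0, 10_000_000, [], DensityParams(flank=300))
        assert -1e-3 < d <= 0

    def test_adjacent_equal_bins_symmetric_and_above_isolated(self):
        p = DensityParams(flank=300)
        iso = density_bias(0, 200, [], p)
        left = density_bias(0, 200, [(200, 400)], p)
        right = density_bias(200, 400, [(0, 200)], p)
        assert left == pytest.approx(right)
        assert left > iso

    def test_smaller_isolated_bins_more_negative(self):
        p = DensityParams(flank=300)
        assert density_bias(0, 100, [], p) < density_bias(0, 200, [], p) < 0

    def test_monotone_in_size_over_grid(self):
        p = DensityParams(flank=300)
        vals = [density_bias(0, s, [], p) for s in range(50, 3000, 50)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_monotone_in_neighbor_proximity(self):
        p = DensityParams(flank=300)
        gaps = [500, 400, 300, 200, 100, 50, 0]
        vals = [density_bias(0, 200, [(200 + g, 400 + g)], p) for g in gaps]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_exact_isolated_value_for_large_bin(self):
        # s >= 2f: shoulder deficit integrates to f/2 per bin
        f, s = 300, 1000
        assert density_bias(0, s, [], DensityParams(flank=f)) == pytest.approx(
            -f / (2 * s)
        )

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            density_bias(10, 10, [])

    def test_density_values_uses_same_chromosome_neighbors_only(self):
        df = pd.DataFrame(
            {
                "chromosome": ["chr1", "chr2"],
                "start": [0, 200],
                "end": [200, 400],
                "gene": ["a", "b"],
            }
        )
        bins = BinTable(df, role="target")
        vals = density_values(bins, DensityParams(flank=300))
        iso = density_bias(0, 200, [], DensityParams(flank=300))
        np.testing.assert_allclose(vals, [iso, iso])


class TestRollingMedianCorrect:
    def test_constant_bias_degenerates_to_median_centering(self):
        vals = np.array([1.0, 2.0, 5.0])
        out = rolling_median_correct(vals, np.zeros(3))
        np.testing.assert_allclose(out, vals - 2.0)

    def test_window_fraction_one_equals_global_centering(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=200)
        bias_v = rng.uniform(size=200)
        out = rolling_median_correct(vals, bias_v, SmootherSpec(window_fraction=1.0))
        np.testing.assert_allclose(out, vals - np.median(vals))

    def test_noiseless_monotone_trend_removed(self):
        rng = np.random.default_rng(1)
        gc = rng.uniform(0.2, 0.8, 1000)
        vals = 2.0 * gc - 1.0  # exact monotone function of the covariate
        spec = SmootherSpec(window_fraction=0.1, min_window=50)
        out = rolling_median_correct(vals, gc, spec)
        # symmetric windows track a monotone trend exactly
        assert np.max(np.abs(out)) <= 1e-12

    def test_retrending_residual_is_zero_for_monotone_input(self):
        rng = np.random.default_rng(2)
        gc = rng.uniform(0.2, 0.8, 500)
        vals = np.tanh(3 * (gc - 0.5))
        spec = SmootherSpec(window_fraction=0.1, min_window=50)
        out = rolling_median_correct(vals, gc, spec)
        again = rolling_median_correct(out, gc, spec)
        assert np.max(np.abs(again - out)) <= 1e-9

    def test_matches_brute_force_window_median_oracle(self):
        rng = np.random.default_rng(3)
        n, w = 200, 50
        vals = rng.normal(size=n)
        bias_v = rng.uniform(size=n)
        spec = SmootherSpec(window_fraction=w / n, min_window=w)
        out = rolling_median_correct(vals, bias_v, spec)
        order = np.lexsort((np.arange(n), bias_v))
        sorted_vals = vals[order]
        trend = np.empty(n)
        h = w // 2
        for i in range(n):  # centered window, symmetric shrinkage at edges
            k = min(h, i, n - 1 - i)
            trend[i] = np.median(sorted_vals[i - k : i + k + 1])
        expect = np.empty(n)
        expect[order] = sorted_vals - trend
        np.testing.assert_allclose(out, expect, atol=1e-12)

    def test_three_smoothers_agree_on_smooth_trend(self):
        rng = np.random.default_rng(4)
        gc = np.sort(rng.uniform(0.2, 0.8, 2000))
        vals = 0.5 * np.sin(6 * gc) + rng.normal(0, 0.02, 2000)
        outs = [
            rolling_median_correct(vals, gc, SmootherSpec(method=m))
            for m in ("rolling_median", "lowess", "kaiser")
        ]
        for a in outs[1:]:
            assert np.median(np.abs(a - outs[0])) < 0.05

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            rolling_median_correct(np.zeros(3), np.zeros(4))


def make_sample(n_on=300, n_off=120, gc_effect=0.0, rmask_effect=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_on):
        rows.append(("chr1", i * 1000, i * 1000 + 200, "GENE", 0.0))
    base = n_on * 1000 + 100_000
    for i in range(n_off):
        rows.append(("chr1", base + i * 50_000, base + (i + 1) * 50_000, ANTITARGET_LABEL, 0.0))
    df = pd.DataFrame(rows, columns=["chromosome", "start", "end", "gene", "log2"])
    df["gc"] = rng.uniform(0.3, 0.7, len(df))
    df["rmask"] = np.where(df["gene"] == ANTITARGET_LABEL, rng.uniform(0, 0.8, len(df)), 0.0)
    df["log2"] = (
        gc_effect * (df["gc"] - 0.5)
        + rmask_effect * df["rmask"]
        + rng.normal(0, 0.05, len(df))
    )
    return BinTable(df, role="coverage")


class TestCorrectTable:
    def test_unbiased_sample_nearly_unchanged(self):
        t = make_sample(seed=1)
        out = correct_table(t)
        assert np.median(np.abs(out.log2 - (t.log2 - np.median(t.log2)))) < 0.05

    def test_gc_bias_removed_per_bin_set(self):
        t = make_sample(gc_effect=1.2, seed=2)
        out = correct_table(t)
        on = out.on_target_mask()
        gc = out.data["gc"].to_numpy()
        for mask in (on, ~on):
            rho = stats.spearmanr(out.log2[mask], gc[mask]).statistic
            assert abs(rho) < 0.15

    def test_repeat_bias_on_targets_untouched_by_repeat_rule(self):
        # inject an rmask-linked effect on *on-target* bins only: the repeat
        # correction must not act there (off-target-only rule)
        t = make_sample(seed=3)
        rng = np.random.default_rng(99)  # independent of the sample's own draws
        on = t.on_target_mask()
        fake_rmask = rng.uniform(0, 0.8, on.sum())
        t.data.loc[on, "rmask"] = fake_rmask
        t.data.loc[on, "log2"] = t.data.loc[on, "log2"] + 0.8 * fake_rmask
        out = correct_table(t)
        rho = stats.spearmanr(
            out.log2[on], out.data["rmask"].to_numpy()[on]
        ).statistic
        # the rmask trend on targets survives (GC/density do not know it)
        assert rho > 0.5

    def test_missing_covariate_rejected(self):
        t = make_sample(seed=4)
        bare = BinTable(t.data.drop(columns=["rmask"]), role="coverage")
        with pytest.raises(TableError, match="rmask"):
            correct_table(bare)

    def test_bin_count_and_order_preserved(self):
        t = make_sample(seed=5)
        out = correct_table(t)
        assert len(out) == len(t)
        assert list(out.start) == list(t.start)
        pd.testing.assert_series_equal(out.data["gene"], t.data["gene"])


class TestCorrectSample:
    def test_covariates_joined_from_profile(self):
        t = make_sample(seed=6)
        on_mask = t.on_target_mask()
        profile = t.copy()
        on = BinTable(t.data.loc[on_mask, ["chromosome", "start", "end", "gene", "log2"]])
        off = BinTable(t.data.loc[~on_mask, ["chromosome", "start", "end", "gene", "log2"]])
        fixed_on, fixed_off = correct_sample(on, off, profile)
        assert len(fixed_on) == on_mask.sum()
        assert len(fixed_off) == (~on_mask).sum()

    def test_sample_bin_missing_from_profile_rejected(self):
        t = make_sample(seed=7)
        on_mask = t.on_target_mask()
        profile = BinTable(t.data.iloc[:-1], role="reference", validate=False)
        on = BinTable(t.data.loc[on_mask, ["chromosome", "start", "end", "gene", "log2"]])
        off = BinTable(t.data.loc[~on_mask, ["chromosome", "start", "end", "gene", "log2"]])
        with pytest.raises(TableError, match="absent"):
            correct_sample(on, off, profile)
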