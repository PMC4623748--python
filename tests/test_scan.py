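"""Tests of the bulked-segregant scan statistics, smoothing and region calling."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import bulkscan as bs
from bulkscan.scan import ScanProfile

depths = st.integers(min_value=0, max_value=500)


class TestSNPIndex:
    @pytest.mark.parametrize("m,p,expected", [(10, 0, 1.0), (5, 5, 0.5), (3, 7, 0.3)])
    def test_values(self, m, p, expected):
        assert bs.snp_index(m, p) == pytest.approx(expected)

    def test_zero_depth_missing(self):
        assert np.isnan(bs.snp_index(0, 0))

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            bs.snp_index(-1, 5)

    @settings(derandomize=True, max_examples=200)
    @given(maa=depths, paa=depths, mab=depths, pab=depths)
    def test_bounds_property(self, maa, paa, mab, pab):
        """SNP-index in [0,1], delta in [-1,1], ED in [0, sqrt(2)] always."""
        aa = bs.snp_index(maa, paa)
        ab = bs.snp_index(mab, pab)
        for idx in (aa, ab):
            assert np.isnan(idx) or 0.0 <= idx <= 1.0
        delta = bs.delta_snp_index(aa, ab)
        if not np.isnan(delta):
            assert -1.0 <= delta <= 1.0
            ed = np.sqrt(2) * abs(delta)
            assert 0.0 <= ed <= np.sqrt(2) + 1e-12


class TestDelta:
    def test_pure_high_parent_bulks_give_plus_one(self):
        assert bs.delta_snp_index(bs.snp_index(30, 0), bs.snp_index(0, 25)) == 1.0

    def test_pure_low_parent_bulks_give_minus_one(self):
        assert bs.delta_snp_index(bs.snp_index(0, 30), bs.snp_index(25, 0)) == -1.0

    def test_equal_indices_give_zero(self):
        assert bs.delta_snp_index(0.37, 0.37) == 0.0

    def test_missing_propagates(self):
        assert np.isnan(bs.delta_snp_index(np.nan, 0.5))


class TestEuclideanDistance:
    def test_maximal_divergence(self):
        assert bs.euclidean_distance([1, 0], [0, 1]) == pytest.approx(np.sqrt(2))

    def test_identical_frequencies(self):
        assert bs.euclidean_distance([0.3, 0.7], [0.3, 0.7]) == 0.0

    def test_closed_form_value(self):
        assert bs.euclidean_distance([0.8, 0.2], [0.5, 0.5]) == pytest.approx(
            0.424264, abs=1e-6
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bs.euclidean_distance([1, 0], [0.5, 0.25, 0.25])

    def test_consistent_with_delta_from_same_depths(self, filtered_markers):
        stats = bs.compute_scan_table(filtered_markers)
        ok = stats.dropna()
        np.testing.assert_allclose(ok["ed"], np.sqrt(2) * ok["delta"].abs())


class TestSlidingWindow:
    def test_single_window_mean(self):
        win = bs.sliding_window([100, 200, 300], [0.1, 0.2, 0.3],
                                window_bp=1000, step_bp=1000)
        assert win["mean"].iloc[0] == pytest.approx(0.2)

    def test_single_marker_window(self):
        win = bs.sliding_window([100], [0.4], window_bp=50, step_bp=10)
        assert win["mean"].tolist() == [0.4]

    def test_empty_window_is_missing(self):
        win = bs.sliding_window([0, 10_000], [0.1, 0.3], window_bp=100, step_bp=1000)
        inner = win.iloc[1:-1]
        assert inner["mean"].isna().all()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(1_000_000, size=500, replace=False)).astype(float)
        val = rng.normal(size=500)
        val[rng.choice(500, 40, replace=False)] = np.nan
        window, step = 60_000.0, 7_000.0
        out = bs.sliding_window(pos, val, window_bp=window, step_bp=step)
        for center, mean in zip(out["center"], out["mean"]):
            inside = (pos >= center - window / 2) & (pos <= center + window / 2)
            sel = val[inside]
            sel = sel[np.isfinite(sel)]
            if sel.size == 0:
                assert np.isnan(mean)
            else:
                assert mean == pytest.approx(sel.mean(), abs=1e-8)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            bs.sliding_window([1], [1.0], window_bp=0)


class TestLoess:
    def test_reproduces_constant(self):
        pos = np.linspace(0, 1000, 30)
        fitted = bs.loess_fit(pos, np.full(30, 0.7))
        np.testing.assert_allclose(fitted, 0.7, atol=1e-10)

    def test_exact_on_linear_input(self):
        pos = np.linspace(0, 1000, 25)
        val = 0.002 * pos - 0.3
        fitted = bs.loess_fit(pos, val, span=1.0)
        np.testing.assert_allclose(fitted, val, atol=1e-8)

    def test_bounded_by_input_range(self):
        rng = np.random.default_rng(3)
        pos = np.arange(200, dtype=float)
        val = np.where(pos < 100, 0.0, 1.0) + rng.normal(0, 0.1, 200)
        fitted = bs.loess_fit(pos, val, span=0.3)
        assert fitted.min() >= val.min() - 1e-9
        assert fitted.max() <= val.max() + 1e-9

    def test_too_few_points_names_chromosome(self):
        with pytest.raises(ValueError, match="chr5"):
            bs.loess_fit([1, 2, 3], [0.1, np.nan, 0.3], chrom="chr5")


class TestThreshold:
    def test_constant_fitted_values(self):
        assert bs.compute_threshold([0.1, 0.1, 0.1], k=1) == pytest.approx(0.1)

    def test_hand_computed_example(self):
        # median 0, sample sd of (0,0,0,1) = 0.5
        assert bs.compute_threshold([0.0, 0.0, 0.0, 1.0], k=1) == pytest.approx(0.5)

    def test_k_zero_is_median(self):
        assert bs.compute_threshold([0.2, 0.4, 0.9], k=0) == pytest.approx(0.4)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            bs.compute_threshold([np.nan, np.nan])


def profile_from_fitted(pos, fitted, threshold, chrom="chr1"):
    markers = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "value": fitted, "fitted": fitted}
    )
    return ScanProfile(
        markers=markers, windows=pd.DataFrame(), statistic="delta", span=0.3,
        window_bp=1e6, step_bp=1e4, k=1.0, genome_median=0.0, genome_sd=0.0,
        threshold=threshold,
    )


class TestRegions:
    def test_run_detection(self):
        prof = profile_from_fitted(
            [1000, 2000, 3000, 4000, 5000], [0.0, 0.0, 0.9, 0.95, 0.0], 0.5
        )
        regions = bs.call_regions(prof)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.n_markers) == (3000, 4000, 2)
        assert r.peak_pos == 4000

    def test_all_below_threshold(self):
        prof = profile_from_fitted([1, 2, 3], [0.1, 0.2, 0.1], 0.5)
        assert bs.call_regions(prof) == []

    def test_strict_inequality_at_threshold(self):
        prof = profile_from_fitted([1, 2, 3], [0.5, 0.5, 0.5], 0.5)
        assert bs.call_regions(prof) == []

    def test_default_simulation_recovers_qtl(self, default_cross, filtered_markers):
        """Top-ranked region of the default cross contains the chr2 QTL."""
        stats = bs.compute_scan_table(filtered_markers)
        prof = bs.compute_profile(stats)
        regions = bs.call_regions(prof, filtered_markers)
        top = regions[0]
        assert top.chrom == "chr2"
        assert top.start <= 4_500_000 <= top.end
        assert top.n_markers >= 1

    def test_ed_statistic_also_recovers_qtl(self, filtered_markers):
        stats = bs.compute_scan_table(filtered_markers)
        prof = bs.compute_profile(stats, statistic="ed")
        regions = bs.call_regions(prof, filtered_markers)
        assert regions[0].chrom == "chr2"


def test_region_invariants_enforced():
    with pytest.raises(ValueError):
        bs.QTLRegion("chr1", 10, 20, 1.0, 25, 3)  # peak outside bounds
    with pytest.raises(ValueError):
        bs.QTLRegion("chr1", 10, 20, 1.0, 15, 0)  # no markers
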