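"""Windowing, feature distances, smoothing, bootstrap and correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import (
    brute_nearest_interval,
    brute_nearest_point,
    brute_overlap_bp,
    brute_partial_spearman,
)
from prdm9kit import recomb


def bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestWindowsAndFiltering:
    def test_windows_tile_from_zero_and_drop_edges(self):
        win = recomb.make_windows({"c1": 100_000}, width=10_000, edge_buffer=10_000)
        assert win["start"].tolist() == [10_000 + i * 10_000 for i in range(8)]
        assert (win["end"] - win["start"]).unique().tolist() == [10_000]

    def test_trailing_partial_window_dropped(self):
        win = recomb.make_windows({"c1": 95_000}, width=10_000, edge_buffer=0)
        assert win["end"].max() == 90_000

    def test_event_well_inside_contig_retained(self):
        ev = bed([("c1", 50_000, 60_000)])
        kept = recomb.filter_events(ev, {"c1": 1_000_000})
        assert len(kept) == 1

    def test_event_near_edge_excluded(self):
        ev = bed([("c1", 5_000, 15_000)])
        assert len(recomb.filter_events(ev, {"c1": 1_000_000})) == 0

    def test_per_event_predicate_on_mixed_set(self):
        ev = bed([
            ("c1", 50_000, 60_000),   # keep
            ("c1", 5_000, 15_000),    # edge
            ("c1", 990_001, 995_000), # edge (end > size - buffer)
            ("c1", 700_000, 710_000), # keep
            ("c1", 9_999, 20_000),    # edge by 1 bp
            ("c1", 10_000, 20_000),   # exactly at buffer: keep
        ])
        kept = recomb.filter_events(ev, {"c1": 1_000_000})
        assert len(kept) == 3

    def test_unknown_contig_errors(self):
        with pytest.raises(ValueError, match="unknown contig"):
            recomb.filter_events(bed([("cX", 0, 10)]), {"c1": 100})


class TestResolutionSummary:
    def test_single_event(self):
        res = recomb.resolution_summary(bed([("c1", 0, 13_000)]))
        assert res["median"] == 13_000

    def test_even_count_median_is_midpoint(self):
        ev = bed([("c1", 0, L) for L in (10_000, 20_000, 30_000, 40_000)])
        res = recomb.resolution_summary(ev)
        assert res["median"] == 25_000

    def test_synthetic_lengths_match_generator_median(self):
        from prdm9kit.simulate import LandscapeConfig, gen_landscape

        land = gen_landscape(
            LandscapeConfig(contig_lengths=(5_000_000,) * 4, n_events=1_000, seed=7)
        )
        res = recomb.resolution_summary(land.events)
        assert res["median"] == pytest.approx(13_000, rel=0.10)
        assert res["q75"] == pytest.approx(35_000, rel=0.15)


class TestAssignment:
    def test_event_inside_one_window_deterministic(self):
        win = recomb.make_windows({"c1": 100_000}, edge_buffer=0)
        ev = bed([("c1", 42_000, 47_000)])
        for seed in range(5):
            assigned, _ = recomb.assign_events_to_windows(ev, win, seed)
            assert assigned.loc[assigned["count"] > 0, "start"].tolist() == [40_000]

    def test_spanning_event_assigned_uniformly(self):
        win = recomb.make_windows({"c1": 100_000}, edge_buffer=0)
        ev = bed([("c1", 35_000, 62_000)])  # spans windows starting 30,40,50,60 kb
        rng = np.random.default_rng(0)
        counts = np.zeros(10)
        n = 4_000
        for _ in range(n):
            assigned, _ = recomb.assign_events_to_windows(ev, win, rng)
            counts += assigned["count"].to_numpy()
        landed = np.nonzero(counts)[0] * 10_000
        assert landed.tolist() == [30_000, 40_000, 50_000, 60_000]
        # each window ~ n/4 with binomial error
        assert stats.chisquare(counts[counts > 0]).pvalue > 1e-4

    def test_counts_conserved_and_rates_sum_to_one(self, rng):
        from prdm9kit.simulate import LandscapeConfig, gen_landscape

        land = gen_landscape(
            LandscapeConfig(contig_lengths=(1_000_000,) * 3, n_events=500, seed=3)
        )
        ev = recomb.filter_events(land.events, land.contig_sizes)
        win = recomb.make_windows(land.contig_sizes)
        assigned, dropped = recomb.assign_events_to_windows(ev, win, rng)
        assert assigned["count"].sum() + dropped == len(ev)
        assert assigned["rate"].sum() == pytest.approx(1.0)

    def test_identical_seed_identical_assignment(self):
        from prdm9kit.simulate import LandscapeConfig, gen_landscape

        land = gen_landscape(
            LandscapeConfig(contig_lengths=(1_000_000,), n_events=200, seed=9)
        )
        ev = recomb.filter_events(land.events, land.contig_sizes)
        win = recomb.make_windows(land.contig_sizes)
        a1, _ = recomb.assign_events_to_windows(ev, win, 42)
        a2, _ = recomb.assign_events_to_windows(ev, win, 42)
        pd.testing.assert_frame_equal(a1, a2)

    def test_event_overlapping_no_retained_window_dropped(self):
        win = recomb.make_windows({"c1": 100_000}, edge_buffer=10_000)
        ev = bed([("c1", 2_000, 6_000)])  # only over the removed edge window
        assigned, dropped = recomb.assign_events_to_windows(ev, win, 0)
        assert dropped == 1
        assert assigned["count"].sum() == 0


class TestFeatureDistance:
    def test_overlap_gives_zero(self):
        win = bed([("c1", 0, 10_000)])
        feats = bed([("c1", 5_000, 5_100)])
        assert recomb.window_feature_distance(win, feats)[0] == 0

    def test_interval_and_midpoint_modes(self):
        win = bed([("c1", 0, 10_000)])
        feats = bed([("c1", 15_000, 15_100)])
        assert recomb.window_feature_distance(win, feats, "interval")[0] == 5_000
        assert recomb.window_feature_distance(win, feats, "midpoint")[0] == 10_000

    def test_nearer_of_two_flanking_features(self):
        win = bed([("c1", 50_000, 60_000)])
        feats = bed([("c1", 10_000, 10_100), ("c1", 63_000, 63_100)])
        assert recomb.window_feature_distance(win, feats)[0] == 3_000

    def test_featureless_chromosome_is_nan(self):
        win = bed([("c1", 0, 10_000), ("c2", 0, 10_000)])
        feats = bed([("c1", 0, 100)])
        d = recomb.window_feature_distance(win, feats)
        assert d[0] == 0 and np.isnan(d[1])

    def test_matches_brute_force_with_overlapping_features(self, rng):
        feats_rows = []
        for _ in range(60):
            s = int(rng.integers(0, 500_000))
            feats_rows.append(("c1", s, s + int(rng.integers(50, 30_000))))
        feats = bed(feats_rows)
        win = recomb.make_windows({"c1": 500_000}, edge_buffer=0)
        pairs = feats[["start", "end"]].to_numpy().tolist()
        d_int = recomb.window_feature_distance(win, feats, "interval")
        d_mid = recomb.window_feature_distance(win, feats, "midpoint")
        for i, (s, e) in enumerate(win[["start", "end"]].to_numpy()):
            assert d_int[i] == brute_nearest_interval(s, e, pairs)
            assert d_mid[i] == brute_nearest_point((s + e) / 2, pairs)


class TestRateByDistance:
    def test_hand_built_bin_means(self):
        dist = np.array([1_000, 2_000, 15_000, 18_000, 25_000, 150_000])
        rate = np.array([0.1, 0.3, 0.2, 0.4, 0.5, 9.9])
        out = recomb.rate_by_distance(dist, rate)
        assert out.loc[0, "mean_rate"] == pytest.approx(0.2)
        assert out.loc[1, "mean_rate"] == pytest.approx(0.3)
        assert out.loc[2, "mean_rate"] == pytest.approx(0.5)
        assert out["n_windows"].sum() == 5  # the 150 kb window is dropped

    def test_uniform_crossovers_give_flat_profile(self):
        from prdm9kit.simulate import LandscapeConfig, gen_landscape

        land = gen_landscape(
            LandscapeConfig(
                contig_lengths=(10_000_000,) * 4, n_events=8_000,
                n_tss=200, seed=21,
            )
        )
        ev = recomb.filter_events(land.events, land.contig_sizes)
        win = recomb.make_windows(land.contig_sizes)
        assigned, _ = recomb.assign_events_to_windows(ev, win, 1)
        d = recomb.window_feature_distance(assigned, land.tss)
        out = recomb.rate_by_distance(d, assigned["rate"].to_numpy())
        means = out["mean_rate"].dropna()
        assert means.max() / means.min() < 2.0

    def test_feature_directed_profile_decreases(self):
        from prdm9kit.simulate import LandscapeConfig, gen_landscape

        land = gen_landscape(
            LandscapeConfig(
                contig_lengths=(10_000_000,) * 4, n_events=8_000,
                n_tss=200, crossover_model="feature", seed=22,
            )
        )
        ev = recomb.filter_events(land.events, land.contig_sizes)
        win = recomb.make_windows(land.contig_sizes)
        assigned, _ = recomb.assign_events_to_windows(ev, win, 1)
        d = recomb.window_feature_distance(assigned, land.tss)
        out = recomb.rate_by_distance(d, assigned["rate"].to_numpy())
        assert out["mean_rate"].iloc[0] > out["mean_rate"].dropna().iloc[-1]

    def test_all_nan_distances_error(self):
        with pytest.raises(ValueError):
            recomb.rate_by_distance(np.array([np.nan]), np.array([0.1]))


class TestLoess:
    def test_constant_rate_scales_to_one_everywhere(self):
        d = np.linspace(0, 100_000, 200)
        r = np.full(200, 0.37)
        grid, fit, scaled = recomb.loess_scale(d, r)
        np.testing.assert_allclose(scaled, 1.0, atol=1e-12)

    def test_linear_relationship_reproduced_exactly(self):
        d = np.linspace(0, 100_000, 300)
        r = 5.0 - 3e-5 * d
        grid, fit, _ = recomb.loess_scale(d, r, span=0.3)
        np.testing.assert_allclose(fit, 5.0 - 3e-5 * grid, atol=1e-6)

    @pytest.mark.parametrize("span", [0.2, 0.3, 0.5])
    def test_linear_exactness_across_spans(self, span):
        d = np.linspace(0, 50_000, 100)
        r = 1.0 + 2e-5 * d
        grid, fit, _ = recomb.loess_scale(d, r, span=span)
        np.testing.assert_allclose(fit, 1.0 + 2e-5 * grid, atol=1e-6)

    def test_last_point_exactly_one(self, rng):
        d = rng.random(100) * 100_000
        r = rng.random(100) + 0.5
        _, _, scaled = recomb.loess_scale(d, r)
        assert scaled[-1] == 1.0

    def test_degenerate_constant_distance_errors(self):
        with pytest.raises(ValueError):
            recomb.loess_scale(np.full(10, 5.0), np.arange(10.0))


class TestBootstrap:
    def _toy(self, rng, n=400):
        d = rng.random(n) * 100_000
        r = rng.random(n) / n
        return d, r

    def test_deterministic_under_seed(self, rng):
        d, r = self._toy(rng)
        a = recomb.bootstrap_binned_means(d, r, B=50, rng=7)
        b = recomb.bootstrap_binned_means(d, r, B=50, rng=7)
        pd.testing.assert_frame_equal(a, b)

    def test_single_resample_collapses_ci(self, rng):
        d, r = self._toy(rng)
        out = recomb.bootstrap_binned_means(d, r, B=1, rng=3)
        np.testing.assert_allclose(out["ci_lo"], out["ci_hi"])

    def test_ci_width_shrinks_with_window_count(self):
        rng = np.random.default_rng(5)
        widths = []
        for n in (500, 2_000):  # 4x more windows
            d = rng.random(n) * 100_000
            r = rng.random(n)
            out = recomb.bootstrap_binned_means(d, r, B=400, rng=11)
            widths.append((out["ci_hi"] - out["ci_lo"]).mean())
        ratio = widths[0] / widths[1]
        assert ratio == pytest.approx(2.0, rel=0.25)

    def test_ci_covers_true_mean_at_nominal_rate(self):
        """~95% of independent datasets should cover the true bin mean."""
        rng = np.random.default_rng(17)
        true_mean = 0.5
        covered = 0
        trials = 200
        for _ in range(trials):
            d = rng.random(300) * 100_000
            r = rng.normal(true_mean, 0.2, 300)
            out = recomb.bootstrap_binned_means(
                d, r, bin_width=100_000, max_distance=100_000, B=200, rng=rng
            )
            covered += out["ci_lo"][0] <= true_mean <= out["ci_hi"][0]
        assert covered / trials == pytest.approx(0.95, abs=0.05)


class TestCorrelate:
    def test_monotone_decreasing_gives_minus_one(self):
        d = np.arange(100, dtype=float)
        r = 1.0 / (d + 1)
        res = recomb.correlate(r, d)
        assert res.rho == pytest.approx(-1.0)

    def test_partial_removes_control_driven_association(self):
        rng = np.random.default_rng(23)
        n = 5_000
        control = rng.random(n) * 100_000
        rate = 1.0 / (control + 1_000) + rng.normal(0, 1e-6, n)
        target = control + rng.normal(0, 10_000, n)  # correlated with control
        plain = recomb.correlate(rate, target)
        partial = recomb.correlate(rate, target, {"ctrl": control})
        assert plain.rho < -0.3
        assert abs(partial.rho) < 0.05

    def test_small_vector_matches_brute_force_partial(self):
        y = [3.0, 1.0, 4.0, 1.5, 5.0, 9.0]
        x = [2.0, 7.0, 1.0, 8.0, 2.5, 8.5]
        c = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        res = recomb.correlate(np.array(y), np.array(x), {"c": np.array(c)})
        expected = brute_partial_spearman(y, x, [c])
        assert res.rho == pytest.approx(expected, abs=1e-10)

    def test_plain_matches_scipy_spearman(self, rng):
        r = rng.random(200)
        d = rng.random(200)
        res = recomb.correlate(r, d)
        rho, p = stats.spearmanr(r, d)
        assert res.rho == pytest.approx(rho)
        assert res.p == pytest.approx(p)

    def test_zero_variance_warns_and_returns_nan(self):
        with pytest.warns(UserWarning):
            res = recomb.correlate(np.ones(10), np.arange(10.0))
        assert np.isnan(res.rho)

    def test_too_few_observations_error(self):
        with pytest.raises(ValueError):
            recomb.correlate(np.ones(3), np.arange(3.0))


class TestPeakOverlapBp:
    def test_peak_covering_whole_window(self):
        win = bed([("c1", 10_000, 20_000)])
        peaks = bed([("c1", 5_000, 25_000)])
        assert recomb.peak_overlap_bp(win, peaks)[0] == 10_000

    def test_peak_straddling_two_windows_splits_exactly(self):
        win = bed([("c1", 0, 10_000), ("c1", 10_000, 20_000)])
        peaks = bed([("c1", 9_800, 10_300)])
        bp = recomb.peak_overlap_bp(win, peaks)
        assert bp.tolist() == [200, 300]
        assert bp.sum() == 500

    def test_no_peaks_on_chromosome_gives_zero(self):
        win = bed([("c2", 0, 10_000)])
        peaks = bed([("c1", 0, 100)])
        assert recomb.peak_overlap_bp(win, peaks)[0] == 0

    def test_overlapping_peaks_not_double_counted(self):
        win = bed([("c1", 0, 10_000)])
        peaks = bed([("c1", 100, 600), ("c1", 300, 900)])
        assert recomb.peak_overlap_bp(win, peaks)[0] == 800

    def test_matches_brute_force(self, rng):
        win = recomb.make_windows({"c1": 200_000}, edge_buffer=0)
        rows = []
        for _ in range(40):
            s = int(rng.integers(0, 199_000))
            rows.append(("c1", s, s + int(rng.integers(50, 5_000))))
        peaks = bed(rows)
        pairs = peaks[["start", "end"]].to_numpy().tolist()
        bp = recomb.peak_overlap_bp(win, peaks)
        for i, (s, e) in enumerate(win[["start", "end"]].to_numpy()):
            assert bp[i] == brute_overlap_bp(int(s), int(e), pairs)
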