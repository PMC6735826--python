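"""Boundary inference: windowing rules, changepoint scan, SNP verification."""

import numpy as np
import pandas as pd
import pytest

from parzev import regions as rg
from parzev import simulate as sim
from parzev.config import SimulationConfig
from parzev.errors import InputError, InsufficientDataError


def make_track(ratios, window=50_000, chrom="chrZ", start0=0):
    n = len(ratios)
    starts = start0 + np.arange(n, dtype=np.int64) * window
    df = pd.DataFrame(
        {
            "start": starts,
            "end": starts + window,
            "mean_depth": 30.0 * np.asarray(ratios),
            "covered_bases": window,
            "gc_fraction": 0.42,
            "normalized_ratio": np.asarray(ratios, dtype=float),
        }
    )
    return rg.WindowTrack(chromosome=chrom, windows=df)


class TestDepthWindows:
    def test_uniform_depth_three_windows(self):
        depth = pd.DataFrame(
            {"chrom": ["chrZ"], "start": [0], "end": [150_000], "depth": [30.0]}
        )
        track = rg.compute_depth_windows(depth)
        assert len(track) == 3
        assert np.allclose(track.windows["mean_depth"], 30.0)

    def test_window_below_min_covered_dropped(self):
        depth = pd.DataFrame(
            {
                "chrom": ["chrZ", "chrZ"],
                "start": [0, 50_000],
                "end": [50_000, 54_000],  # second window only 4 kb covered
                "depth": [30.0, 30.0],
            }
        )
        track = rg.compute_depth_windows(depth)
        assert list(track.windows["start"]) == [0]

    def test_split_window_mean_is_weighted(self):
        depth = pd.DataFrame(
            {
                "chrom": ["chrZ", "chrZ"],
                "start": [0, 25_000],
                "end": [25_000, 50_000],
                "depth": [30.0, 10.0],
            }
        )
        track = rg.compute_depth_windows(depth)
        assert track.windows["mean_depth"].iloc[0] == pytest.approx(20.0)

    def test_overlapping_input_rejected(self):
        depth = pd.DataFrame(
            {
                "chrom": ["chrZ", "chrZ"],
                "start": [0, 10_000],
                "end": [20_000, 30_000],
                "depth": [30.0, 30.0],
            }
        )
        with pytest.raises(InputError):
            rg.compute_depth_windows(depth)

    def test_mean_matches_per_base_oracle(self):
        rng = np.random.default_rng(0)
        edges = np.sort(rng.choice(np.arange(1, 200_000), 40, replace=False))
        edges = np.concatenate([[0], edges, [200_000]])
        depth = pd.DataFrame(
            {
                "chrom": "chrZ",
                "start": edges[:-1],
                "end": edges[1:],
                "depth": rng.uniform(5, 50, len(edges) - 1),
            }
        )
        track = rg.compute_depth_windows(depth, window_size=50_000, min_covered=0)
        per_base = np.repeat(depth["depth"].to_numpy(), (depth["end"] - depth["start"]))
        for _, row in track.windows.iterrows():
            assert row["mean_depth"] == pytest.approx(
                per_base[int(row["start"]) : int(row["end"])].mean()
            )


class TestNormalize:
    def test_ratio_is_depth_over_autosomal_median(self):
        z = make_track([1.0])
        z.windows["mean_depth"] = 15.0
        auto = make_track([1.0] * 10, chrom="chr4")
        out = rg.normalize_depth(z, [auto])
        assert out.windows["normalized_ratio"].iloc[0] == pytest.approx(0.5)

    def test_gc_correct_identity_when_gc_constant(self):
        rng = np.random.default_rng(1)
        z = make_track(rng.uniform(0.9, 1.1, 50))
        auto = make_track(rng.uniform(0.9, 1.1, 200), chrom="chr4")
        plain = rg.normalize_depth(z, [auto], gc_correct=False)
        corrected = rg.normalize_depth(z, [auto], gc_correct=True)
        assert np.allclose(
            plain.windows["normalized_ratio"], corrected.windows["normalized_ratio"]
        )

    def test_gc_correct_reduces_variance_under_gc_trend(self):
        c = SimulationConfig(
            seed=2, z_length=20_000_000, gc_depth_slope=3.0, gc_sd=0.05,
            autosome_lengths={"chr4": 30_000_000},
        )
        layout = sim.simulate_layout(c)
        cov = sim.simulate_coverage(layout, c, "female")
        par_end = layout.true_boundary
        plain = rg.normalize_depth(cov["chrZ"], [cov["chr4"]], gc_correct=False)
        corr = rg.normalize_depth(cov["chrZ"], [cov["chr4"]], gc_correct=True)
        in_par = plain.windows["end"] <= par_end
        v_plain = plain.windows.loc[in_par, "normalized_ratio"].var()
        v_corr = corr.windows.loc[in_par, "normalized_ratio"].var()
        assert v_corr < v_plain

    def test_zero_baseline_rejected(self):
        z = make_track([1.0] * 5)
        auto = make_track([0.0] * 5, chrom="chr4")
        auto.windows["mean_depth"] = 0.0
        with pytest.raises(InputError):
            rg.normalize_depth(z, [auto])


class TestCoverageBoundary:
    def test_exact_changepoint_noise_free(self):
        track = make_track([1.0] * 800 + [0.5] * 700)
        ann = rg.infer_boundary_from_coverage(track)
        assert ann.boundary_bp == 40_000_000
        assert ann.dr_interval == (40_000_000, 75_000_000)
        assert ann.dr_mean_ratio == pytest.approx(0.5)
        assert ann.support == (800, 700)

    def test_flat_track_reports_no_dr(self):
        rng = np.random.default_rng(3)
        track = make_track(rng.normal(1.0, 0.03, 300))
        ann = rg.infer_boundary_from_coverage(track)
        assert ann.no_dr
        assert ann.boundary_bp is None
        assert "no-DR" in ann.flags

    def test_mirror_equivariance(self):
        rng = np.random.default_rng(4)
        ratios = np.concatenate(
            [rng.normal(1.0, 0.08, 80), rng.normal(0.5, 0.04, 60)]
        )
        ann_fwd = rg.infer_boundary_from_coverage(make_track(ratios))
        ann_rev = rg.infer_boundary_from_coverage(make_track(ratios[::-1]))
        n = len(ratios)
        # the split index must mirror: k_rev = n - k_fwd
        k_fwd = ann_fwd.boundary_bp // 50_000
        k_rev = ann_rev.boundary_bp // 50_000
        assert k_fwd + k_rev == n
        assert ann_rev.dr_interval[0] == 0

    def test_changepoint_matches_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(4, 200))
            v = rng.normal(0, 1, n)
            k, sse = rg.two_segment_changepoint(v, min_run=1)
            best = min(
                range(1, n),
                key=lambda j: np.sum((v[:j] - v[:j].mean()) ** 2)
                + np.sum((v[j:] - v[j:].mean()) ** 2),
            )
            sse_best = np.sum((v[:best] - v[:best].mean()) ** 2) + np.sum(
                (v[best:] - v[best:].mean()) ** 2
            )
            assert sse == pytest.approx(sse_best)

    def test_too_few_windows_raises(self):
        with pytest.raises(InsufficientDataError):
            rg.infer_boundary_from_coverage(make_track([1.0] * 15), min_run=10)

    def test_short_dr_run_reports_no_dr(self):
        track = make_track([1.0] * 100 + [0.5] * 5)
        ann = rg.infer_boundary_from_coverage(track, min_run=10)
        assert ann.no_dr


class TestExpressionWindows:
    @staticmethod
    def genes(ratios, spacing=100_000):
        n = len(ratios)
        starts = np.arange(n) * spacing
        return pd.DataFrame(
            {"start": starts, "end": starts + 10_000, "ratio": ratios}
        )

    def test_forty_unit_ratio_genes_two_zero_windows(self):
        win = rg.compute_mf_expression_windows(self.genes([1.0] * 40))
        assert len(win) == 2
        assert np.allclose(win["mean_log2"], 0.0)

    def test_twenty_double_ratio_genes_one_window(self):
        win = rg.compute_mf_expression_windows(self.genes([2.0] * 20))
        assert len(win) == 1
        assert win["mean_log2"].iloc[0] == pytest.approx(1.0)

    def test_step_between_windows(self):
        win = rg.compute_mf_expression_windows(self.genes([1.0] * 100 + [1.5] * 100))
        step = win["mean_log2"].iloc[5] - win["mean_log2"].iloc[4]
        assert step == pytest.approx(np.log2(1.5))

    def test_trailing_window_kept_if_half_full(self):
        assert len(rg.compute_mf_expression_windows(self.genes([1.0] * 30))) == 2
        assert len(rg.compute_mf_expression_windows(self.genes([1.0] * 25))) == 1

    def test_empty_and_invalid_inputs(self):
        with pytest.raises(InputError):
            rg.compute_mf_expression_windows(self.genes([]))
        with pytest.raises(InputError):
            rg.compute_mf_expression_windows(self.genes([1.0, -2.0]))


class TestExpressionBoundary:
    def test_step_boundary_found(self):
        win = rg.compute_mf_expression_windows(
            TestExpressionWindows.genes([1.0] * 100 + [1.5] * 100)
        )
        ann = rg.infer_boundary_from_expression(win)
        assert ann.boundary_bp == 100 * 100_000
        assert ann.dr_mean_ratio == pytest.approx(1.5)

    def test_flat_reports_no_dr(self):
        win = rg.compute_mf_expression_windows(TestExpressionWindows.genes([1.0] * 100))
        ann = rg.infer_boundary_from_expression(win)
        assert ann.no_dr

    def test_too_few_windows_raises(self):
        win = rg.compute_mf_expression_windows(TestExpressionWindows.genes([1.0] * 60))
        with pytest.raises(InsufficientDataError):
            rg.infer_boundary_from_expression(win)


class TestSnpDensity:
    def test_af_band_is_inclusive_and_filters(self):
        v = pd.DataFrame(
            {
                "chrom": "chrZ",
                "pos": [10, 20, 30, 40, 50],
                "af": [0.1, 0.2, 0.5, 0.8, 0.9],
            }
        )
        track = rg.snp_density_track(v, window_size=100)
        assert track["count"].iloc[0] == 3  # 0.2, 0.5, 0.8 kept

    def test_counts_per_window(self):
        v = pd.DataFrame(
            {"chrom": "chrZ", "pos": [1, 2, 3, 4, 5, 60_000], "af": [0.5] * 6}
        )
        track = rg.snp_density_track(v)
        assert track["count"].iloc[0] == 5
        assert track["count"].iloc[1] == 1

    def test_exon_restricted_matches_brute_force(self):
        rng = np.random.default_rng(6)
        pos = np.sort(rng.choice(200_000, 500, replace=False))
        v = pd.DataFrame({"chrom": "chrZ", "pos": pos, "af": rng.beta(20, 20, 500)})
        starts = np.arange(0, 200_000, 4_000)
        exons = pd.DataFrame({"start": starts, "end": starts + rng.integers(500, 3000, len(starts))})
        track = rg.snp_density_track(v, window_size=50_000, exons=exons)
        # brute-force recount per window over exonic positions only
        in_exon = np.zeros(200_000, bool)
        for s, e in exons.itertuples(index=False):
            in_exon[s:e] = True
        kept = v[(v["af"] >= 0.2) & (v["af"] <= 0.8) & in_exon[v["pos"]]]
        for w in range(4):
            expected = ((kept["pos"] // 50_000) == w).sum()
            assert track["count"].iloc[w] == expected
            exonic_bp = in_exon[w * 50_000 : (w + 1) * 50_000].sum()
            assert track["exonic_bp"].iloc[w] == exonic_bp

    def test_chrom_length_extends_zero_windows(self):
        v = pd.DataFrame({"chrom": "chrZ", "pos": [100], "af": [0.5]})
        track = rg.snp_density_track(v, window_size=50_000, chrom_length=500_000)
        assert len(track) == 10
        assert track["count"].sum() == 1


class TestSnpVerification:
    @staticmethod
    def annotation():
        return rg.RegionAnnotation(
            chromosome="chrZ",
            boundary_bp=500_000,
            par_interval=(0, 500_000),
            dr_interval=(500_000, 1_000_000),
            method="coverage",
        )

    @staticmethod
    def density(par_counts, dr_counts, window=50_000):
        counts = list(par_counts) + list(dr_counts)
        starts = np.arange(len(counts)) * window
        return pd.DataFrame({"start": starts, "end": starts + window, "count": counts})

    def test_empty_dr_is_consistent(self):
        d = self.density([5] * 10, [0] * 10)
        out = rg.verify_boundary_with_snps(self.annotation(), d)
        assert "snp-consistent" in out.flags

    def test_uniform_density_is_ambiguous(self):
        d = self.density([5] * 10, [5] * 10)
        out = rg.verify_boundary_with_snps(self.annotation(), d)
        assert "snp-ambiguous" in out.flags

    def test_leaky_dr_flags_elevated(self):
        d = self.density([10] * 10, [3] * 10)
        out = rg.verify_boundary_with_snps(self.annotation(), d)
        assert "snp-elevated-DR" in out.flags

    def test_simulated_leak_raises_elevated_flag(self, small_config):
        c = SimulationConfig(**{**small_config.to_dict(), "dr_leak_rate": 3e-5})
        layout = sim.simulate_layout(c)
        v = sim.simulate_female_variants(layout, c)
        track = rg.snp_density_track(
            v, chrom="chrZ", chrom_length=c.z_length
        )
        ann = rg.RegionAnnotation(
            chromosome="chrZ",
            boundary_bp=layout.true_boundary,
            par_interval=(0, layout.true_boundary),
            dr_interval=(layout.true_boundary, c.z_length),
            method="coverage",
        )
        out = rg.verify_boundary_with_snps(ann, track)
        assert "snp-elevated-DR" in out.flags


class TestEndToEndBoundary:
    def test_noise_free_boundaries_equal_truth(self):
        c = SimulationConfig(
            seed=9, z_length=20_000_000, depth_cv=0.0, nb_dispersion=0.0,
            autosome_lengths={"chr4": 20_000_000},
        )
        layout = sim.simulate_layout(c)
        cov = sim.simulate_coverage(layout, c, "female")
        z = rg.normalize_depth(cov["chrZ"], [cov["chr4"]])
        ann = rg.infer_boundary_from_coverage(z)
        # truth falls inside the boundary window
        assert abs(ann.boundary_bp - layout.true_boundary) < c.window_size
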