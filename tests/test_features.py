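"""Codon-usage statistics, interval densities, intron sizes, contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from parzev import features as ft
from parzev.errors import InputError, UndefinedValueError


class TestGc3s:
    def test_all_gc_third_positions(self):
        assert ft.gc3s(ft.CodingSequence("g", "GGCGGG")) == 1.0

    def test_all_at_third_positions(self):
        assert ft.gc3s(ft.CodingSequence("g", "GGAGGT")) == 0.0

    def test_met_trp_only_is_undefined(self):
        with pytest.raises(UndefinedValueError):
            ft.gc3s(ft.CodingSequence("g", "ATGTGG"))

    def test_met_trp_excluded_from_denominator(self):
        # ATG (excluded) + GGC (G) + GGA (A) -> 1/2
        assert ft.gc3s(ft.CodingSequence("g", "ATGGGCGGA")) == pytest.approx(0.5)

    def test_n_containing_codons_excluded(self):
        assert ft.gc3s(ft.CodingSequence("g", "GGNGGC")) == 1.0

    def test_invariant_under_codon_shuffle(self):
        rng = np.random.default_rng(0)
        codons = ["".join(rng.choice(list("ACGT"), 3)) for _ in range(300)]
        codons = [c for c in codons if c not in ft.STOP_CODONS]
        seq = "".join(codons)
        shuffled = [codons[i] for i in rng.permutation(len(codons))]
        assert ft.gc3s(ft.CodingSequence("a", seq)) == pytest.approx(
            ft.gc3s(ft.CodingSequence("b", "".join(shuffled)))
        )

    def test_frame_violation_rejected(self):
        with pytest.raises(InputError):
            ft.CodingSequence("g", "GGCGG")

    def test_internal_stop_warns(self):
        with pytest.warns(UserWarning):
            ft.CodingSequence("g", "GGCTAAGGC")


def uniform_usage_cds(copies=4):
    """Every sense codon of every synonymous family, `copies` times."""
    codons = []
    for fam in ft.SYN_FAMILIES.values():
        if len(fam) > 1:
            codons.extend(list(fam) * copies)
    return "".join(codons)


def single_codon_cds(copies=3):
    """Exactly one codon per amino acid (maximal bias)."""
    codons = []
    for fam in ft.SYN_FAMILIES.values():
        codons.extend([fam[0]] * copies)
    return "".join(codons)


def brute_force_enc(seq):
    """Independent ENC computation, straight from the homozygosity formula."""
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    codons = [c for c in codons if "N" not in c and c not in ft.STOP_CODONS]
    fbar = {}
    for size in (2, 3, 4, 6):
        fs = []
        for fam in ft.SYN_FAMILIES.values():
            if len(fam) != size:
                continue
            counts = [codons.count(c) for c in fam]
            n = sum(counts)
            if n < 2:
                continue
            f = (n * sum((x / n) ** 2 for x in counts) - 1) / (n - 1)
            if f > 0:
                fs.append(f)
        if fs:
            fbar[size] = sum(fs) / len(fs)
    order = [2, 3, 4, 6]
    for k in order:
        if k not in fbar:
            below = [c for c in order if c < k and c in fbar]
            above = [c for c in order if c > k and c in fbar]
            nb = ([below[-1]] if below else []) + ([above[0]] if above else [])
            fbar[k] = float(np.mean([fbar[c] for c in nb]))
    enc = 2 + 9 / fbar[2] + 1 / fbar[3] + 5 / fbar[4] + 3 / fbar[6]
    return min(max(enc, 20.0), 61.0)


class TestEnc:
    def test_uniform_usage_clamps_to_61(self):
        assert ft.enc(ft.CodingSequence("g", uniform_usage_cds())) == 61.0

    def test_single_codon_per_amino_acid_is_20(self):
        assert ft.enc(ft.CodingSequence("g", single_codon_cds())) == 20.0

    def test_matches_brute_force_on_random_codons(self):
        rng = np.random.default_rng(1)
        sense = [c for fam in ft.SYN_FAMILIES.values() for c in fam]
        for _ in range(5):
            seq = "".join(rng.choice(sense, 1000))
            expected = brute_force_enc(seq)
            assert ft.enc(ft.CodingSequence("g", seq)) == pytest.approx(
                expected, abs=1e-9
            )

    def test_duplication_effect_vanishes_with_length(self):
        # the homozygosity estimator carries an O(1/n) bias-correction term,
        # so duplicating a CDS shifts ENC by an amount that must decay to 0
        rng = np.random.default_rng(2)
        sense = [c for fam in ft.SYN_FAMILIES.values() for c in fam]

        def dup_shift(n):
            seq = "".join(rng.choice(sense, n))
            return abs(
                ft.enc(ft.CodingSequence("g", seq))
                - ft.enc(ft.CodingSequence("g", seq * 2))
            )

        short, long = dup_shift(500), dup_shift(10_000)
        assert long < short
        assert long < 0.2

    def test_uniform_background_equals_uncorrected(self):
        rng = np.random.default_rng(3)
        sense = [c for fam in ft.SYN_FAMILIES.values() for c in fam]
        seq = "".join(rng.choice(sense, 600))
        bg = {b: 0.25 for b in "ACGT"}
        plain = ft.enc(ft.CodingSequence("g", seq))
        corrected = ft.enc(
            ft.CodingSequence("g", seq, background_freqs=bg), use_background=True
        )
        assert corrected == pytest.approx(plain, abs=1e-9)

    def test_gc_matched_background_raises_enc(self):
        # a GC3-skewed gene looks biased to plain ENC; against a background
        # with the same skew the apparent bias shrinks (ENC' > ENC)
        rng = np.random.default_rng(4)
        fams = [f for f in ft.SYN_FAMILIES.values() if len(f) > 1]
        codons = []
        for fam in fams:
            gc_members = [c for c in fam if c[2] in "GC"] or list(fam)
            codons.extend(rng.choice(gc_members, 50))
        seq = "".join(codons)
        bg = ft.nucleotide_freqs(seq)
        plain = ft.enc(ft.CodingSequence("g", seq))
        corrected = ft.enc(
            ft.CodingSequence("g", seq, background_freqs=bg), use_background=True
        )
        assert corrected > plain

    def test_background_required_when_requested(self):
        with pytest.raises(InputError):
            ft.enc(ft.CodingSequence("g", "GGCGGG"), use_background=True)

    def test_missing_class_fallback_used(self):
        # only 2-fold families present (Lys: AAA/AAG); still yields a value
        value = ft.enc(ft.CodingSequence("g", "AAA" * 5 + "AAG" * 5))
        assert 20.0 <= value <= 61.0


class TestIntervalDensity:
    def windows(self, n=4, size=50_000):
        starts = np.arange(n, dtype=np.int64) * size
        return pd.DataFrame({"start": starts, "end": starts + size})

    def test_single_te_fraction(self):
        te = pd.DataFrame({"start": [10_000], "end": [15_000]})
        d = ft.interval_density_windows(te, self.windows())
        assert d[0] == pytest.approx(0.1)

    def test_duplicate_intervals_merged(self):
        te = pd.DataFrame({"start": [10_000, 10_000], "end": [15_000, 15_000]})
        d = ft.interval_density_windows(te, self.windows())
        assert d[0] == pytest.approx(0.1)

    def test_straddling_interval_split_proportionally(self):
        te = pd.DataFrame({"start": [47_000], "end": [52_000]})  # 3 kb + 2 kb
        d = ft.interval_density_windows(te, self.windows())
        assert d[0] == pytest.approx(3_000 / 50_000)
        assert d[1] == pytest.approx(2_000 / 50_000)

    def test_conservation_against_per_base_oracle(self):
        rng = np.random.default_rng(5)
        starts = rng.integers(0, 190_000, 60)
        te = pd.DataFrame({"start": starts, "end": starts + rng.integers(100, 9_000, 60)})
        win = self.windows()
        d = ft.interval_density_windows(te, win)
        covered = np.zeros(250_000, bool)
        for s, e in te.itertuples(index=False):
            covered[s:e] = True
        for i, row in win.iterrows():
            assert d[i] * 50_000 == pytest.approx(
                covered[row["start"] : row["end"]].sum()
            )
        total_in_grid = covered[: win["end"].max()].sum()
        assert np.sum(d * 50_000) == pytest.approx(total_in_grid)

    def test_empty_intervals_zero_density(self):
        d = ft.interval_density_windows(pd.DataFrame({"start": [], "end": []}), self.windows())
        assert np.allclose(d, 0.0)


class TestIntronSizes:
    def test_two_exon_gene(self):
        # 1-based inclusive exons 1-100 and 201-300 == internal [0,100),[200,300)
        out = ft.intron_sizes({"g": [[(0, 100), (200, 300)]]})
        assert out["g"] == [100]

    def test_single_exon_gene_empty(self):
        assert ft.intron_sizes({"g": [[(0, 500)]]})["g"] == []

    def test_longest_transcript_wins(self):
        short = [(0, 50), (100, 150)]
        long = [(0, 200), (500, 700), (900, 1100)]
        out = ft.intron_sizes({"g": [short, long]})
        assert out["g"] == [300, 200]

    def test_overlapping_exons_skipped(self):
        out = ft.intron_sizes({"bad": [[(0, 100), (50, 200)]], "ok": [[(0, 10), (20, 30)]]})
        assert "bad" not in out
        assert out["ok"] == [10]

    def test_matches_brute_force_gap_scan(self):
        rng = np.random.default_rng(6)
        models = {}
        for i in range(50):
            n_ex = int(rng.integers(1, 9))
            bounds = np.sort(rng.choice(100_000, 2 * n_ex, replace=False))
            exons = [(int(bounds[2 * j]), int(bounds[2 * j + 1])) for j in range(n_ex)]
            models[f"g{i}"] = [exons]
        out = ft.intron_sizes(models)
        for gid, exons in ((g, m[0]) for g, m in models.items()):
            expected = [exons[j + 1][0] - exons[j][1] for j in range(len(exons) - 1)]
            assert out[gid] == expected


class TestRegionFeatureTest:
    def test_identical_multisets_p_one(self):
        res = ft.region_feature_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    def test_all_tied_p_one(self):
        res = ft.region_feature_test([5.0, 5.0, 5.0], [5.0, 5.0])
        assert res.p_value == 1.0

    def test_extreme_separation_matches_exact_enumeration(self):
        res = ft.region_feature_test([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
        # exact two-sided rank-sum: most extreme of C(6,3)=20 splits, both tails
        assert res.p_value == pytest.approx(2 / 20)
        # p = 0.1 > alpha, so no directional call despite the median gap
        assert res.direction == "ns"
        assert res.medians == (2.0, 102.0)

    def test_power_on_shifted_lognormals(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(20):
            a = rng.lognormal(np.log(2000 * 1.3), 0.8, 500)
            b = rng.lognormal(np.log(2000), 0.8, 500)
            res = ft.region_feature_test(a, b)
            hits += res.p_value < 0.05 and res.direction == "faster"
        assert hits >= 16  # >= 80% power

    def test_small_groups_rejected(self):
        with pytest.raises(InputError):
            ft.region_feature_test([1.0], [2.0, 3.0])


class TestSizeCorrelation:
    def test_perfectly_linear(self):
        xs = [(1e6, 1.0), (2e6, 2.0), (3e6, 3.0)]
        r, p = ft.chromosome_size_correlation(xs)
        assert r == pytest.approx(1.0)
        r, p = ft.chromosome_size_correlation([(s, -v) for s, v in xs])
        assert r == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(8)
        sizes = rng.uniform(1e7, 2e8, 10)
        vals = 0.5 * sizes / 1e8 + rng.normal(0, 0.1, 10)
        r, p = ft.chromosome_size_correlation(list(zip(sizes, vals)))
        x, y = sizes - sizes.mean(), vals - vals.mean()
        r_manual = np.sum(x * y) / np.sqrt(np.sum(x**2) * np.sum(y**2))
        assert r == pytest.approx(r_manual)

    def test_spearman_option(self):
        xs = [(1e6, 1.0), (2e6, 10.0), (3e6, 100.0), (4e6, 1000.0)]
        r, p = ft.chromosome_size_correlation(xs, method="spearman")
        assert r == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InputError):
            ft.chromosome_size_correlation([(1e6, 1.0), (2e6, 2.0)])
        with pytest.raises(UndefinedValueError):
            ft.chromosome_size_correlation([(1e6, 1.0), (2e6, 1.0), (3e6, 1.0)])


class TestSimulatedMonotonicity:
    def test_te_density_tracks_configured_class_density(self, small_config):
        from parzev import simulate as sim
        from parzev.config import SimulationConfig

        c = SimulationConfig(**{
            **small_config.to_dict(),
            "te_density_by_class": {"PAR": 0.15, "DR": 0.12, "CHR4": 0.06, "CHR5": 0.03},
        })
        layout = sim.simulate_layout(c)
        medians = {}
        for chrom, klass in (("chrZ", "PAR"), ("chr4", "CHR4"), ("chr5", "CHR5")):
            size = layout.length(chrom)
            hi = layout.true_boundary if klass == "PAR" else size
            starts = np.arange(0, hi - 50_000, 50_000, dtype=np.int64)
            grid = pd.DataFrame({"start": starts, "end": starts + 50_000})
            te = layout.te_intervals
            sub = te[te["chrom"] == chrom]
            medians[klass] = float(
                np.median(ft.interval_density_windows(sub[["start", "end"]], grid))
            )
        assert medians["PAR"] > medians["CHR4"] > medians["CHR5"]
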