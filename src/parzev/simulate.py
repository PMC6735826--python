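"""Synthetic genomes, tracks, divergence tables, variants, and expression.

The generator produces every input the analysis consumes, with the
statistical structure the analysis assumes: a Z chromosome split into a
recombining PAR and a differentiated region (DR) at a single boundary
(optionally two, kiwi-like), half-depth female coverage and absent female
heterozygosity in the DR, region-specific dN/dS, incomplete dosage
compensation, and size-matched autosomal reference chromosomes.  Every
downstream stage therefore has a ground truth to be checked against.

All coordinates are 0-based half-open internally; format conventions are
applied only when serializing (GFF3/VCF 1-based, BED/bedGraph 0-based).
Identical configurations (including the seed) give bit-identical outputs:
each operation derives its own generator from (seed, operation-tag), so
running one operation never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import config as cfg
from .config import SimulationConfig, PAR, DR, classify_chromosome
from .errors import ConfigurationError
from .expression import ExpressionMatrix
from .regions import WindowTrack

_OP_TAGS = {
    "layout": 1,
    "coverage_female": 2,
    "coverage_male": 3,
    "divergence": 4,
    "expression": 5,
    "variants": 6,
    "cds": 7,
}


def _rng(config: SimulationConfig, op: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _OP_TAGS[op]])


@dataclass
class Gene:
    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: List[tuple]
    region_class: str

    @property
    def exon_bp(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class GenomeAnnotation:
    """Ground-truth layout: chromosomes, region classes, genes, TEs, GC."""

    chromosomes: List[tuple]  # (name, length, [(start, end, class), ...])
    genes: List[Gene]
    te_intervals: pd.DataFrame  # chrom, start, end
    true_boundary: int
    gc: Dict[str, np.ndarray] = field(default_factory=dict)  # per-window GC
    window_size: int = 50_000

    def class_intervals(self, chrom: str) -> List[tuple]:
        for name, _, intervals in self.chromosomes:
            if name == chrom:
                return intervals
        raise KeyError(chrom)

    def length(self, chrom: str) -> int:
        for name, length, _ in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def class_at(self, chrom: str, pos: int) -> str:
        for start, end, klass in self.class_intervals(chrom):
            if start <= pos < end:
                return klass
        raise ValueError(f"position {pos} outside {chrom}")

    def genes_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "chrom": [g.chromosome for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "region_class": [g.region_class for g in self.genes],
                "exon_bp": [g.exon_bp for g in self.genes],
            }
        )


# ---------------------------------------------------------------------------
# layout


def simulate_layout(config: SimulationConfig) -> GenomeAnnotation:
    """Partition chromosomes into region classes and place genes and TEs.

    The Z carries a PAR block of ``par_fraction`` of its length followed by
    the DR (plus an optional distal second PAR); autosomes are single-class.
    Gene counts per chromosome are Poisson(genes_per_mb x Mb); exon counts
    are uniform on 2-12; exon and intron sizes are lognormal, intron scale
    being region-class specific so intron-size contrasts are emulatable.
    TE intervals are placed uniformly per class at class-specific density.
    """
    config.validate()
    rng = _rng(config, "layout")

    boundary = int(round(config.par_fraction * config.z_length))
    z_intervals = [(0, boundary, PAR)]
    if config.second_par_fraction > 0:
        second = int(round(config.second_par_fraction * config.z_length))
        z_intervals.append((boundary, config.z_length - second, DR))
        z_intervals.append((config.z_length - second, config.z_length, PAR))
    else:
        z_intervals.append((boundary, config.z_length, DR))
    chromosomes = [("chrZ", config.z_length, z_intervals)]
    for name, length in sorted(config.autosome_lengths.items()):
        chromosomes.append((name, int(length), [(0, int(length), classify_chromosome(name))]))

    layout = GenomeAnnotation(
        chromosomes=chromosomes,
        genes=[],
        te_intervals=pd.DataFrame({"chrom": [], "start": [], "end": []}),
        true_boundary=boundary,
        window_size=config.window_size,
    )

    genes: List[Gene] = []
    for name, length, _ in chromosomes:
        n_genes = int(rng.poisson(config.genes_per_mb * length / 1e6))
        starts = np.sort(rng.integers(0, max(length - 1, 1), size=n_genes))
        for i, start in enumerate(starts):
            klass = layout.class_at(name, int(start))
            n_exons = int(rng.integers(2, 13))
            exon_lens = np.maximum(
                30, rng.lognormal(np.log(config.exon_mean), config.exon_sigma, n_exons)
            ).astype(int)
            intron_mean = config.intron_mean_by_class.get(klass, 1500.0)
            intron_lens = np.maximum(
                60, rng.lognormal(np.log(intron_mean), config.intron_sigma, n_exons - 1)
            ).astype(int)
            span = int(exon_lens.sum() + intron_lens.sum())
            gstart = int(min(start, max(length - span - 1, 0)))
            exons = []
            pos = gstart
            for j, el in enumerate(exon_lens):
                exons.append((pos, pos + int(el)))
                pos += int(el)
                if j < n_exons - 1:
                    pos += int(intron_lens[j])
            genes.append(
                Gene(
                    gene_id=f"{name}_g{i:05d}",
                    chromosome=name,
                    start=gstart,
                    end=pos,
                    strand="+" if rng.random() < 0.5 else "-",
                    exons=exons,
                    region_class=layout.class_at(name, gstart),
                )
            )
    layout.genes = genes

    te_rows = []
    mean_len = config.te_mean_len * float(np.exp(config.te_len_sigma**2 / 2))
    for name, length, intervals in chromosomes:
        for start, end, klass in intervals:
            density = config.te_density_by_class.get(klass, 0.08)
            span = end - start
            n_te = int(round(density * span / mean_len))
            if n_te == 0:
                continue
            te_start = rng.integers(start, end, size=n_te)
            te_len = np.maximum(
                50, rng.lognormal(np.log(config.te_mean_len), config.te_len_sigma, n_te)
            ).astype(int)
            te_end = np.minimum(te_start + te_len, end)
            for s, e in zip(np.sort(te_start), te_end[np.argsort(te_start, kind="stable")]):
                if e > s:
                    te_rows.append((name, int(s), int(e)))
    layout.te_intervals = pd.DataFrame(te_rows, columns=["chrom", "start", "end"])

    # per-window GC is a genome property shared by male and female tracks
    for name, length, _ in chromosomes:
        n_win = (length + config.window_size - 1) // config.window_size
        layout.gc[name] = np.clip(
            rng.normal(config.gc_mean, config.gc_sd, n_win), 0.25, 0.65
        )
    return layout


# ---------------------------------------------------------------------------
# coverage


def simulate_coverage(
    layout: GenomeAnnotation, config: SimulationConfig, sex: str
) -> Dict[str, WindowTrack]:
    """Windowed read-depth tracks for one sex.

    Female DR windows have expected depth ``depth_mean / 2`` (reads from the
    degenerate W fail to map); everything else, and all male windows, have
    expected depth ``depth_mean``.  Noise is multiplicative lognormal with
    the configured CV (depth cannot go negative); an optional linear GC
    trend ``1 + gc_depth_slope x (GC - 0.5)`` scales the expectation.
    """
    if sex not in ("male", "female"):
        raise ConfigurationError(f"sex must be 'male' or 'female', got {sex!r}")
    rng = _rng(config, f"coverage_{sex}")
    w = config.window_size
    sigma = float(np.sqrt(np.log1p(config.depth_cv**2)))
    out: Dict[str, WindowTrack] = {}
    for name, length, intervals in layout.chromosomes:
        n_win = (length + w - 1) // w
        starts = np.arange(n_win, dtype=np.int64) * w
        ends = np.minimum(starts + w, length)
        mids = (starts + ends) // 2
        gc = layout.gc.get(name, np.full(n_win, config.gc_mean))[:n_win]

        expected = np.full(n_win, config.depth_mean)
        if sex == "female":
            classes = np.array([layout.class_at(name, int(m)) for m in mids])
            expected = np.where(classes == DR, config.depth_mean / 2.0, expected)
        expected = expected * (1.0 + config.gc_depth_slope * (gc - 0.5))
        if config.depth_cv > 0:
            noise = np.exp(rng.normal(-sigma**2 / 2.0, sigma, n_win))
        else:
            noise = np.ones(n_win)
        depth = expected * noise
        df = pd.DataFrame(
            {
                "start": starts,
                "end": ends,
                "mean_depth": depth,
                "covered_bases": (ends - starts).astype(np.int64),
                "gc_fraction": gc,
            }
        )
        out[name] = WindowTrack(chromosome=name, windows=df)
    return out


# ---------------------------------------------------------------------------
# divergence


def simulate_divergence_table(
    layout: GenomeAnnotation, config: SimulationConfig
) -> pd.DataFrame:
    """Per-gene substitution counts under region-specific dN/dS.

    Synonymous sites are 25% of CDS length (nonsynonymous 75%); each gene
    gets a lineage rate r ~ Gamma(ds_shape, ds_mean/ds_shape) (mean
    ``ds_mean``), then S-subs ~ Poisson(r x S-sites) and N-subs ~
    Poisson(omega_class x r x N-sites).  Because both site counts are
    proportional to CDS length, the aggregated ratio-of-sums omega is
    centered exactly on the configured class omega.
    """
    rng = _rng(config, "divergence")
    present = {g.region_class for g in layout.genes}
    missing = present - set(config.omega_by_class)
    if missing:
        raise ConfigurationError(f"omega_by_class missing classes: {sorted(missing)}")
    rows = []
    for g in layout.genes:
        cds_len = max((g.exon_bp // 3) * 3, 90)
        s_sites = 0.25 * cds_len
        n_sites = 0.75 * cds_len
        rate = (
            rng.gamma(config.ds_shape, config.ds_mean / config.ds_shape)
            if config.ds_mean > 0
            else 0.0
        )
        omega = config.omega_by_class[g.region_class]
        s_subs = float(rng.poisson(rate * s_sites))
        n_subs = float(rng.poisson(omega * rate * n_sites))
        rows.append(
            {
                "gene_id": g.gene_id,
                "chromosome": g.chromosome,
                "region_class": g.region_class,
                "start": g.start,
                "n_sites": n_sites,
                "s_sites": s_sites,
                "n_subs": n_subs,
                "s_subs": s_subs,
                "dn": n_subs / n_sites,
                "ds": s_subs / s_sites,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression


def simulate_expression_counts(
    layout: GenomeAnnotation, config: SimulationConfig, n_replicates_per_sex: int = 3
) -> ExpressionMatrix:
    """Negative-binomial counts with a dosage effect on DR genes.

    Baseline gene means are lognormal; DR genes' male mean is
    ``dosage_ratio_dr`` times the female mean (incomplete dosage
    compensation seen from the male side); a ``sexbias_fraction`` of
    non-DR genes is truly sex-biased with fold ``sexbias_fold`` (half male-,
    half female-biased).  ``nb_dispersion`` is the NB2 dispersion; zero
    gives the deterministic noise-free calibration mode in which counts
    equal their expectations exactly.  Per-sample library factors are drawn
    in [1/library_factor, library_factor].
    """
    if n_replicates_per_sex < 1:
        raise ConfigurationError("n_replicates_per_sex must be >= 1")
    rng = _rng(config, "expression")
    genes = layout.genes
    n_genes = len(genes)
    base = rng.lognormal(config.expr_log_mean, config.expr_log_sd, n_genes)

    is_dr = np.array([g.region_class == DR for g in genes])
    bias_fold = np.ones(n_genes)
    non_dr = np.flatnonzero(~is_dr)
    n_biased = int(round(config.sexbias_fraction * non_dr.size))
    if n_biased > 0:
        chosen = rng.choice(non_dr, size=n_biased, replace=False)
        half = n_biased // 2
        bias_fold[chosen[:half]] = config.sexbias_fold  # male-biased
        bias_fold[chosen[half:]] = 1.0 / config.sexbias_fold  # female-biased

    mu_f = base
    mu_m = base * np.where(is_dr, config.dosage_ratio_dr, bias_fold)

    sample_ids, sexes, columns = [], [], []
    f = max(config.library_factor, 1.0)
    for sex, mu in (("M", mu_m), ("F", mu_f)):
        for rep in range(1, n_replicates_per_sex + 1):
            lib = rng.uniform(1.0 / f, f) if f > 1.0 else 1.0
            mean = mu * lib
            if config.nb_dispersion > 0:
                r = 1.0 / config.nb_dispersion
                p = r / (r + mean)
                counts = rng.negative_binomial(r, p)
            else:
                counts = mean  # noise-free calibration mode
            sample_ids.append(f"{sex}{rep}")
            sexes.append(sex)
            columns.append(counts)

    counts_df = pd.DataFrame(
        np.column_stack(columns),
        index=[g.gene_id for g in genes],
        columns=sample_ids,
    )
    lengths = pd.Series([max(g.exon_bp, 90) for g in genes], index=counts_df.index)
    samples = pd.DataFrame(
        {"sex": sexes, "tissue": "brain", "replicate": [int(s[1:]) for s in sample_ids]},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    region = pd.Series([g.region_class for g in genes], index=counts_df.index)
    truth = pd.Series(np.where(is_dr, config.dosage_ratio_dr, bias_fold), index=counts_df.index)
    return ExpressionMatrix(
        counts=counts_df,
        lengths=lengths,
        samples=samples,
        region_class=region,
        true_sex_bias=truth,
    )


# ---------------------------------------------------------------------------
# variants


def simulate_female_variants(
    layout: GenomeAnnotation, config: SimulationConfig
) -> pd.DataFrame:
    """Female heterozygous sites: present in PAR/autosomes, absent in the DR.

    Sites arrive as a Poisson process at ``het_rate_par`` per bp outside the
    DR and ``dr_leak_rate`` inside it (emulating degenerate-W reads
    mismapping onto the Z).  Allele frequencies are Beta(20, 20): centred on
    0.5 with most mass inside the (0.2, 0.8) heterozygote band.
    """
    rng = _rng(config, "variants")
    rows = []
    for name, _, intervals in layout.chromosomes:
        for start, end, klass in intervals:
            rate = config.dr_leak_rate if klass == DR else config.het_rate_par
            n = int(rng.poisson(rate * (end - start)))
            if n == 0:
                continue
            pos = np.sort(rng.integers(start, end, size=n))
            af = rng.beta(20.0, 20.0, size=n)
            for p, a in zip(pos, af):
                rows.append((name, int(p), float(a)))
    return pd.DataFrame(rows, columns=["chrom", "pos", "af"])


# ---------------------------------------------------------------------------
# coding sequence


_SENSE_CODONS = None


def _sense_codons():
    global _SENSE_CODONS
    if _SENSE_CODONS is None:
        from .features import STOP_CODONS

        bases = "TCAG"
        _SENSE_CODONS = [
            a + b + c
            for a in bases
            for b in bases
            for c in bases
            if a + b + c not in STOP_CODONS
        ]
    return _SENSE_CODONS


def simulate_cds_sequences(
    layout: GenomeAnnotation, config: SimulationConfig
) -> Dict[str, str]:
    """Random in-frame CDS per gene with class-specific third-position GC.

    Codons are sampled from the 61 sense codons with weights favouring
    G/C third positions at probability ``gc3_by_class[class]``; the CDS
    length is the gene's exonic length floored to a codon multiple.  The
    sequences carry no homology signal, only the composition structure the
    codon-usage statistics consume.
    """
    rng = _rng(config, "cds")
    codons = _sense_codons()
    third_gc = np.array([c[2] in "GC" for c in codons])
    out: Dict[str, str] = {}
    for g in layout.genes:
        gc3 = config.gc3_by_class.get(g.region_class, 0.5)
        w = np.where(third_gc, gc3 / third_gc.sum(), (1.0 - gc3) / (~third_gc).sum())
        w = w / w.sum()
        n_codons = max(g.exon_bp // 3, 30)
        idx = rng.choice(len(codons), size=n_codons, p=w)
        out[g.gene_id] = "".join(codons[i] for i in idx)
    return out
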