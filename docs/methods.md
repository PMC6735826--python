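# Methods

`parzev` analyzes the evolution of an avian-style ZW sex-chromosome system in
which the Z chromosome is split into a pseudoautosomal region (PAR), which
still recombines in both sexes and is diploid in females, and a
differentiated region (DR), whose W-linked homolog has degenerated so that
females are functionally hemizygous. This note describes the models and
procedures the package implements, the assumptions behind them, and the
choices made where the design was genuinely open.

## Region annotation

### Coverage-based boundary

In a female, reads from the degenerate W no longer map to the DR of the Z, so
female read depth in the DR is expected at half the autosomal level, while the
PAR stays at full depth. The package computes mean depth in fixed windows
(default 50 kb; windows with fewer than 5 kb of covered sequence are dropped),
normalizes each Z window by the median autosomal window depth, and locates the
PAR/DR transition with an exhaustive two-segment least-squares changepoint
scan over the normalized ratios (O(n) via cumulative sums; ties break to the
leftmost split).

The qualitative rule "where the half-coverage pattern starts" is made testable
with three acceptance conditions, all tunable:

- the putative DR segment mean must lie in `dr_band = [0.35, 0.65]`;
- the PAR segment mean should lie in `par_band = [0.8, 1.2]` (violations are
  flagged, not fatal);
- the DR run must span at least `min_run = 10` windows.

If the DR conditions fail, the chromosome is reported as having no detectable
DR. The boundary is reported at window resolution — the start of the first
window of the changed segment — with the window width as its uncertainty; the
data do not identify the exact base pair. The estimator is equivariant under
chromosome mirroring (a distal PAR yields the mirrored split).

An optional GC correction divides each window's depth by the median autosomal
depth of its 2%-GC bin instead of the global median; it is off by default
because the half-coverage signal is robust to moderate GC-coverage trends, and
on simulated GC-confounded tracks it strictly reduces PAR ratio variance (a
tested property). A recursive binary-segmentation mode with a BIC stopping
rule (`segment_boundaries_recursive`) exists for chromosomes that may carry a
second PAR; it is off by default.

### Expression-based boundary

Without global dosage compensation, DR genes are expressed higher in males
(two Z copies) than females (one). Per-gene log2 male/female ratios of
normalized expression are averaged in consecutive windows of 20 genes
(configurable; 10 is a common alternative and a trailing window is kept when
at least half full), and the same two-segment scan is applied to the window
means. The higher segment is the DR and must reach `dr_min_log2 = 0.2`; the
boundary is reported as the start of the first gene of the first DR window.
Windowing matters: individual genes can be sex-biased or retain W expression,
but chromosome-scale shifts of the windowed mean are not produced by
gene-level effects.

### SNP verification

Because females are hemizygous for the DR, female heterozygosity should vanish
there. Variants with allele frequency in [0.2, 0.8] (inclusive) are counted in
the same 50 kb grid (optionally per exonic bp when only RNA-seq variants are
available). A boundary is flagged `snp-consistent` when the DR median count is
at most 5% of the PAR median, `snp-elevated-DR` between 5% and 80% (the
signature of partially degenerate W reads mismapping onto the Z), and
`snp-ambiguous` otherwise. The two fractions are package defaults for a
qualitative rule; the flags expose the evidence and do not adjudicate
ambiguous cases.

## Divergence analysis

Per-gene nonsynonymous/synonymous substitution and site counts (e.g. parsed
from codeml free-ratio branch tables, for which a reader is provided) are
aggregated per region as ratios of sums: dN = Σ N-subs / Σ N-sites, dS =
Σ S-subs / Σ S-sites, ω = dN/dS. This is a length-weighted estimator; it never
divides by a tiny per-gene dS and differs from the mean of per-gene ratios
whenever site counts differ across genes (a tested case). ω is undefined
(flagged) when the aggregate dS is zero. Genes whose total substitution count
(nonsynonymous + synonymous, summed) strictly exceeds 1,500 are removed first
as saturation/alignment artifacts; removal counts are logged.

Uncertainty comes from resampling genes:

- **Bootstrap.** Genes are resampled with replacement (default 1,000
  replicates) and the aggregate statistic recomputed; the percentile interval
  is reported by default, with BCa (jackknife acceleration) behind a flag.
  Replicates with undefined ω are discarded; more than 50% undefined is an
  error. Simulated coverage of the 95% interval for ω is 93–97% at 2,000
  genes (a tested property).
- **Permutation.** Region-vs-reference contrasts permute gene labels over the
  pooled set, preserving group sizes, and compare the aggregated-statistic
  difference two-sidedly. The add-one estimator p = (1 + #{|T_perm| ≥
  |T_obs|}) / (n_perm + 1) keeps p in (0, 1] and ≥ 1/(n_perm+1). Small groups
  can be enumerated exhaustively, in which case the plain proportion over all
  distinct splits is returned. Under null simulations the rejection rate at
  α = 0.05 sits inside the 99% binomial band (tested). Gene-length strata are
  not preserved during permutation; since the statistic is already
  length-weighted, stratification would second-guess the estimator, and the
  pooled-label null is the one the add-one estimator is exact for.

The faster-Z report runs {Z, PAR, DR} × {dN, dS, ω} against a pooled chr4+chr5
reference (size-matched macrochromosomes; per-chromosome references are
available), calling "faster"/"slower" at α = 0.05. A robustness mode drops
Z-linked genes within a configured distance of the inferred boundary and
recomputes everything, guarding against boundary misannotation contaminating
the PAR with young-DR genes.

## Genomic features

- **GC3s** — the G+C fraction at third positions of codons belonging to
  synonymous families; Met, Trp, stop codons, and codons containing N are
  excluded. Used as a proxy for GC-biased gene conversion and hence
  recombination rate.
- **ENC** — Wright's effective number of codons, ENC = 2 + 9/F̄₂ + 1/F̄₃ +
  5/F̄₄ + 3/F̄₆, with per-family homozygosity F = (nΣp̂² − 1)/(n − 1). Six-fold
  families (Leu, Ser, Arg) are kept whole, stop codons are excluded, families
  with n < 2 (or non-positive F) are dropped, and a degeneracy class with no
  estimable family borrows the mean of its nearest estimable classes. The
  result is clamped to [20, 61]. With background correction the homozygosity
  is replaced by the chi-square deviation from codon frequencies expected
  under the gene's intron nucleotide composition, F′ = (χ² + n − m)/(m(n−1));
  this reduces exactly to F under a uniform background (tested). Note that
  the n−1 bias correction makes the *estimator* length-dependent:
  duplicating a CDS shifts ENC by O(1/n) (≈6 units at 200 codons, ≈0.1 at
  10,000), although the estimand is scale-invariant.
- **Interval densities** (TE, exon) — intervals are merged before summing, so
  duplicated annotations cannot inflate density; intervals straddling window
  edges contribute only the overlapping bp. Total covered bp is conserved
  across the grid (tested against a per-base oracle).
- **Intron sizes** — gaps between consecutive exons of the transcript with the
  greatest total exon length (multi-transcript genes); genes with overlapping
  exons are skipped with a warning. Log-transformation happens only at
  comparison time.

Region contrasts use the two-sided Wilcoxon rank-sum test; fully tied inputs
return p = 1. Chromosome-size correlations default to Pearson on
per-chromosome summaries (Spearman available; the choice is configurable
because either is defensible for three to ten chromosomes).

## Expression analysis

### Normalization

TPM (count/length, scaled to 1e6 per sample) is provided as the basic unit.
For male/female comparisons the pipeline instead uses median-of-ratios size
factors with the reference restricted to non-Z genes, then divides by gene
length. The reason is library composition: when ~20% of genes (the DR) are
systematically male-inflated, per-sample totals — and hence TPM — absorb part
of that signal and bias every ratio downward by the DR's expression share
(~0.09 log2 units at default simulation conditions). A size-factor reference
of autosomal genes is invariant to the dosage effect under study. With equal
libraries and no dosage effect the two normalizations agree.

### Dosage compensation

Per-gene log2 M/F ratios (mean across replicates per sex, pseudocount 0.01,
genes below 1 unit of normalized expression in both sexes dropped) are
summarized per region class by median and mean, with back-transformed ratios.
A "partial compensation" flag is set when the DR median log2 ratio lies
strictly between 0 (full compensation) and 1 (no compensation). At the
default simulated ratio of 1.4 the DR median is recovered within ±0.1 log2
units with ~500 DR genes and 3 replicates per sex (tested); the residual
downward bias of a few hundredths is the Jensen effect of the log of noisy
replicate means.

### Sex-biased genes

Differential expression between sexes is a deliberately simple, calibrated
stand-in for a full DE package — external per-gene results (gene_id, lfc,
qvalue) are accepted as a drop-in replacement. Counts are size-factor
normalized, log2-transformed with a 0.5 pseudocount, and tested with an
empirical-Bayes moderated t-statistic: per-gene pooled variances are shrunk
toward a running-mean variance trend over average log-expression, with prior
degrees of freedom estimated by the method of moments on log sample variances
(scaled inverse-chi-square prior). Genes under 10 normalized counts in both
sexes are not tested (independent filtering of the skew-dominated stratum).
Benjamini–Hochberg controls the FDR at 5%.

This design was chosen after measuring two simpler candidates at 3 replicates
per sex: a negative-binomial Wald test with moment dispersions referred to a
normal produced false discoveries in 92/100 null simulations (moment
dispersions are far too noisy at n = 3), and the same statistic referred to
t(4) had ~1% power at 4-fold changes. The moderated t is calibrated in the
tail (empirical P(p < 0.001) ≈ 0.001 under the null) with ~100% power at
4-fold changes and n = 3.

Enrichment of sex-biased genes in PAR, DR, or the whole Z relative to
autosomes uses Fisher's exact test on the (biased, unbiased) × (region,
autosomes) table, run separately per bias direction; degenerate margins give
p = 1 with an undefined odds ratio, flagged.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes — not
any particular sequencing experiment. Its defaults are the package's study
conditions:

| parameter | default | meaning |
|---|---|---|
| z_length | 75 Mb | Z chromosome size |
| par_fraction | 0.5 | PAR share of the Z (single boundary; optional distal second PAR) |
| autosome_lengths | chr4 = 97 Mb, chr5 = 63 Mb | size-matched reference chromosomes |
| window_size | 50 kb | depth/SNP window grid |
| depth_mean, depth_cv | 30×, 0.08 | windowed depth and its noise (lognormal, mean-preserving) |
| gc_depth_slope | 0 | optional linear GC-coverage confounder, 1 + slope·(GC − 0.5) |
| omega_by_class | 0.13 everywhere | true dN/dS per region class |
| ds_mean, ds_shape | 0.05, 2 | mean and gamma shape of per-gene lineage rates |
| genes_per_mb | 8 | Poisson gene density |
| dosage_ratio_dr | 1.4 | true DR male/female expression ratio (in [1, 2]) |
| nb_dispersion | 0.05 | NB2 count dispersion; 0 = deterministic calibration mode |
| het_rate_par / dr_leak_rate | 1e-4 / 0 | female het sites per bp outside/inside the DR |

Depth noise is multiplicative lognormal (depth cannot go negative) with the
mean correction exp(−σ²/2) so expectations are exact. Divergence counts are
Poisson around gamma-distributed gene rates; because synonymous and
nonsynonymous site counts are both proportional to CDS length, the
ratio-of-sums ω is centred exactly on the configured class ω. Expression
counts are NB2 with gene-wise lognormal baselines; DR genes' male means are
multiplied by the dosage ratio, and an optional fraction of non-DR genes is
truly sex-biased. Allele frequencies of heterozygous sites are Beta(20, 20),
centred on 0.5 with most mass inside the [0.2, 0.8] band. Coding sequences
are random sense codons with class-specific third-position GC propensity.
Per-window GC is a genome property drawn once in the layout, shared by male
and female coverage tracks.

What the generator does **not** emulate: read-level noise and mapping
artifacts, W-chromosome assembly contamination beyond the `dr_leak_rate`
knob, linkage between neighbouring genes, fixed per-library sequencing totals
(counts are gene-wise independent, so there is no compositional competition
beyond the configured library factors), tissue effects, or sequence homology
(CDS sequences carry composition only). Passing tests therefore demonstrate
that the estimators recover the signals they target under the assumed
statistical structure — not that real libraries are free of the mapping and
assembly pathologies the flags are designed to surface.

Determinism: every operation derives its generator from (seed, operation
tag), so identical configurations give bit-identical outputs and running one
operation never perturbs another.

## Numerical and procedural choices

- Internal coordinates are 0-based half-open everywhere; GFF3/VCF (1-based)
  are converted at the I/O edge only, involutively. Strand is recorded but
  never used to flip coordinates.
- Changepoint ties break to the smallest split index; the scan equals
  brute-force enumeration on every input (tested to 200 windows).
- JSON reports serialize with sorted keys, fixed float formatting, and no
  timestamps, so identical runs are byte-identical; provenance records the
  scientific-config hash (paths excluded), per-stage seeds, and input file
  checksums.
- Problem sizes in the test-suite and acceptance-script replicate studies
  (e.g. 100–500 replicates, 150–300 bootstrap-coverage runs, 20 Mb genomes
  for expression pattern studies) are the package's chosen simulation scale:
  large enough that the binomial bands on the tested rates are meaningful,
  small enough to keep a full verification run to about a minute per study.

## Known limitations

- The exact base pair of the PAR/DR transition is not identifiable from 50 kb
  windows; all boundary statements carry window-width uncertainty.
- The DE stand-in tests each gene marginally and does not model tissue or
  batch structure; for real analyses plug in external DE results.
- The kiwi-like two-boundary case is generated and segmentable (recursive
  mode), but the pipeline's default annotation assumes a single boundary and
  will return the dominant transition with flags, not a multi-PAR model.
- Fisher's exact test treats genes as exchangeable units; clustering of
  co-regulated neighbours would make its p-values optimistic on real data.
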