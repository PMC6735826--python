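"""Configuration objects for simulation and the analysis pipeline.

A single YAML file can drive both the synthetic-data generator and the
analysis, so an end-to-end run is a single command.  All generative
distributional choices (lognormal depth noise, gamma gene-rate variation,
negative-binomial counts, ...) are stand-ins: the statistical structure the
analysis assumes is what is being emulated, not any particular sequencing
experiment.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

from .errors import ConfigurationError

# Region classes used throughout the package.
PAR = "PAR"
DR = "DR"
CHR4 = "CHR4"
CHR5 = "CHR5"
AUTOSOME_MACRO = "AUTOSOME_MACRO"
OTHER = "OTHER"

#: classes making up the Z chromosome
Z_CLASSES = (PAR, DR)
#: default autosomal reference classes (size-matched macrochromosomes)
REFERENCE_CLASSES = (CHR4, CHR5)


def _default_omega() -> dict:
    return {PAR: 0.13, DR: 0.13, CHR4: 0.13, CHR5: 0.13}


def _default_autosomes() -> dict:
    return {"chr4": 97_000_000, "chr5": 63_000_000}


def _default_te_density() -> dict:
    # higher TE load on the Z than on size-matched autosomes
    return {PAR: 0.12, DR: 0.12, CHR4: 0.08, CHR5: 0.07}


def _default_intron_mean() -> dict:
    # bp; PAR/DR introns larger than autosomal ones
    return {PAR: 2200.0, DR: 2200.0, CHR4: 1500.0, CHR5: 1500.0}


def _default_gc3() -> dict:
    # third-position GC propensity used when sampling coding sequence
    return {PAR: 0.45, DR: 0.50, CHR4: 0.55, CHR5: 0.55}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic genome/expression/divergence generator.

    Defaults describe a ZW bird with a ~75 Mb Z chromosome carrying a single
    PAR/DR boundary, size-matched macrochromosomes chr4 (97 Mb) and chr5
    (63 Mb), half-depth female coverage in the DR, absent female
    heterozygosity in the DR, and incomplete dosage compensation (DR
    male/female expression ratio strictly between 1 and 2).
    """

    seed: int = 0
    z_length: int = 75_000_000
    par_fraction: float = 0.5
    second_par_fraction: float = 0.0  # >0 gives a kiwi-like second PAR at the far end
    autosome_lengths: dict = field(default_factory=_default_autosomes)
    window_size: int = 50_000

    # read-depth track
    depth_mean: float = 30.0
    depth_cv: float = 0.08
    gc_depth_slope: float = 0.0
    gc_mean: float = 0.42
    gc_sd: float = 0.03

    # divergence table
    omega_by_class: dict = field(default_factory=_default_omega)
    ds_mean: float = 0.05
    ds_shape: float = 2.0  # gamma shape of among-gene rate variation

    # gene structure
    genes_per_mb: float = 8.0
    exon_mean: float = 170.0
    exon_sigma: float = 0.6
    intron_mean_by_class: dict = field(default_factory=_default_intron_mean)
    intron_sigma: float = 0.8

    # expression
    dosage_ratio_dr: float = 1.4
    sexbias_fraction: float = 0.0
    sexbias_fold: float = 4.0
    nb_dispersion: float = 0.05
    expr_log_mean: float = 5.0  # ln scale of expected counts
    expr_log_sd: float = 1.2
    library_factor: float = 1.0  # per-sample depth factors drawn in [1/f, f]

    # female variants
    het_rate_par: float = 1e-4
    dr_leak_rate: float = 0.0

    # transposable elements
    te_density_by_class: dict = field(default_factory=_default_te_density)
    te_mean_len: float = 800.0
    te_len_sigma: float = 0.7

    # coding sequence sampling
    gc3_by_class: dict = field(default_factory=_default_gc3)

    def validate(self) -> "SimulationConfig":
        if not 0 < self.par_fraction < 1:
            raise ConfigurationError(f"par_fraction must be in (0,1), got {self.par_fraction}")
        if self.second_par_fraction < 0 or self.par_fraction + self.second_par_fraction >= 1:
            raise ConfigurationError("par_fraction + second_par_fraction must be < 1")
        if self.z_length <= 0 or any(v <= 0 for v in self.autosome_lengths.values()):
            raise ConfigurationError("chromosome lengths must be positive")
        if not 1.0 <= self.dosage_ratio_dr <= 2.0:
            raise ConfigurationError(
                f"dosage_ratio_dr must lie in [1, 2], got {self.dosage_ratio_dr}"
            )
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        if self.window_size <= 0:
            raise ConfigurationError("window_size must be positive")
        if self.depth_cv < 0 or self.depth_mean <= 0:
            raise ConfigurationError("depth parameters out of range")
        if self.het_rate_par < 0 or self.dr_leak_rate < 0:
            raise ConfigurationError("variant rates must be >= 0")
        if self.ds_mean < 0:
            raise ConfigurationError("ds_mean must be >= 0")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown simulation parameters: {sorted(unknown)}")
        return cls(**d).validate()


@dataclass
class AnalysisConfig:
    """Knobs of the analysis stages (windowing, resampling, thresholds)."""

    window_size: int = 50_000
    min_covered: int = 5_000
    mf_window_genes: int = 20
    reference_chromosomes: tuple = ("chr4", "chr5")
    n_boot: int = 1000
    n_perm: int = 1000
    fdr: float = 0.05
    alpha: float = 0.05
    max_total_subs: float = 1500.0
    gc_correct: bool = False
    multi_boundary: bool = False
    use_background_enc: bool = False
    boundary_exclusion_bp: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["reference_chromosomes"] = list(self.reference_chromosomes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "reference_chromosomes" in d:
            d["reference_chromosomes"] = tuple(d["reference_chromosomes"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown analysis parameters: {sorted(unknown)}")
        return cls(**d)


@dataclass
class PipelineConfig:
    """Everything needed for one end-to-end run.

    ``inputs`` maps logical names (depth_female, depth_male, gc_track, genes_gff,
    vcf, counts, samples, divergence, te_bed, regions_bed, cds_fasta) to file
    paths.  Stages whose inputs are absent are skipped and marked "not run" in
    the report.
    """

    seed: int = 0
    outdir: str = "parzev_out"
    simulation: Optional[SimulationConfig] = None
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    inputs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "outdir": self.outdir,
            "simulation": self.simulation.to_dict() if self.simulation else None,
            "analysis": self.analysis.to_dict(),
            "inputs": dict(self.inputs),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sim = d.get("simulation")
        return cls(
            seed=int(d.get("seed", 0)),
            outdir=str(d.get("outdir", "parzev_out")),
            simulation=SimulationConfig.from_dict(sim) if sim else None,
            analysis=AnalysisConfig.from_dict(d.get("analysis", {})),
            inputs=dict(d.get("inputs", {})),
        )

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (seed, simulation, analysis).

        Paths (outdir, input locations) are excluded: two runs of the same
        analysis in different directories are the same analysis, and input
        content is checksummed separately in the report's provenance block.
        """
        d = self.to_dict()
        d.pop("outdir", None)
        d.pop("inputs", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def classify_chromosome(name: str) -> str:
    """Region class for a whole (autosomal) chromosome name."""
    if name.lower() in ("chr4", "4"):
        return CHR4
    if name.lower() in ("chr5", "5"):
        return CHR5
    return AUTOSOME_MACRO
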