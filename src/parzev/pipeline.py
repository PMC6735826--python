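"""End-to-end orchestration: simulate, parse, analyze, report.

Stage order mirrors the analysis logic: annotate PAR/DR regions from female
depth (cross-checked with expression ratios and female SNP density), then
quantify dosage compensation and sex-biased-gene enrichment, then run the
faster-Z / faster-PAR / faster-DR divergence contrasts, then the
genomic-feature contrasts.  Stages whose inputs are absent are marked
"not run".  Everything is deterministic under the configured seed, and the
JSON report serializes byte-identically across repeated runs (no
timestamps; fixed key order).
"""

from __future__ import annotations

import json
import logging
import os
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import config as cfg
from . import divergence as dv
from . import expression as ex
from . import features as ft
from . import io as pio
from . import regions as rg
from . import simulate as sim
from .config import AnalysisConfig, PipelineConfig, SimulationConfig, classify_chromosome
from .errors import InputError

log = logging.getLogger(__name__)

Z_CHROM = "chrZ"

BUNDLE_FILES = {
    "depth_female": "female.depth.bedGraph",
    "depth_male": "male.depth.bedGraph",
    "gc_track": "gc.bedGraph",
    "genes_gff": "genes.gff3",
    "vcf": "female.vcf",
    "counts": "counts.tsv",
    "samples": "samples.tsv",
    "gene_lengths": "gene_lengths.tsv",
    "divergence": "divergence.tsv",
    "te_bed": "te.bed",
    "regions_bed": "regions.bed",
    "cds_fasta": "cds.fa",
    "truth": "truth.json",
}


def write_bundle(config: SimulationConfig, outdir: str, n_replicates_per_sex: int = 3) -> dict:
    """Simulate a full input bundle and serialize it to ``outdir``.

    Returns the inputs mapping suitable for :class:`PipelineConfig`.
    """
    pio.ensure_dir(outdir)
    layout = sim.simulate_layout(config)
    paths = {k: os.path.join(outdir, v) for k, v in BUNDLE_FILES.items()}

    female = sim.simulate_coverage(layout, config, "female")
    male = sim.simulate_coverage(layout, config, "male")
    pio.write_bedgraph(
        pd.concat([pio.windowtrack_to_bedgraph_df(t) for t in female.values()]),
        paths["depth_female"],
    )
    pio.write_bedgraph(
        pd.concat([pio.windowtrack_to_bedgraph_df(t) for t in male.values()]),
        paths["depth_male"],
    )
    gc_rows = []
    for name, length, _ in layout.chromosomes:
        gc = layout.gc[name]
        starts = np.arange(len(gc), dtype=np.int64) * config.window_size
        ends = np.minimum(starts + config.window_size, length)
        gc_rows.append(
            pd.DataFrame({"chrom": name, "start": starts, "end": ends, "depth": gc})
        )
    pio.write_bedgraph(pd.concat(gc_rows), paths["gc_track"])

    pio.write_gff3(layout.genes, paths["genes_gff"])
    pio.write_bed(layout.te_intervals, paths["te_bed"])
    region_rows = []
    for name, _, intervals in layout.chromosomes:
        for s, e, klass in intervals:
            region_rows.append((name, s, e, klass))
    pio.write_bed(
        pd.DataFrame(region_rows, columns=["chrom", "start", "end", "name"]),
        paths["regions_bed"],
    )
    contigs = {name: length for name, length, _ in layout.chromosomes}
    pio.write_vcf(sim.simulate_female_variants(layout, config), paths["vcf"], contigs)
    pio.write_divergence_tsv(sim.simulate_divergence_table(layout, config), paths["divergence"])

    matrix = sim.simulate_expression_counts(layout, config, n_replicates_per_sex)
    pio.write_counts_tsv(matrix.counts, paths["counts"])
    pio.write_sample_sheet(matrix.samples, paths["samples"])
    pio.write_gene_lengths_tsv(matrix.lengths, paths["gene_lengths"])
    pio.write_fasta(sim.simulate_cds_sequences(layout, config), paths["cds_fasta"])

    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "true_boundary": layout.true_boundary,
                "config": config.to_dict(),
                "n_genes": len(layout.genes),
            },
            fh,
            sort_keys=True,
            indent=2,
        )
    return paths


# ---------------------------------------------------------------------------


def parse_inputs(pconfig: PipelineConfig) -> dict:
    """Read and validate every referenced input file into memory."""
    inputs = pconfig.inputs
    data: Dict[str, object] = {}

    def has(key: str) -> bool:
        return key in inputs and inputs[key] and os.path.exists(inputs[key])

    for key in inputs:
        if inputs[key] and not os.path.exists(inputs[key]):
            raise InputError(f"input {key} not found: {inputs[key]}")

    if has("depth_female"):
        data["depth_female"] = pio.read_bedgraph(inputs["depth_female"])
    if has("depth_male"):
        data["depth_male"] = pio.read_bedgraph(inputs["depth_male"])
    if has("gc_track"):
        gc = pio.read_bedgraph(inputs["gc_track"])
        data["gc_track"] = gc.rename(columns={"depth": "gc"})
    if has("genes_gff"):
        data["genes"] = pio.read_gff3_genes(inputs["genes_gff"])
    if has("vcf"):
        data["variants"] = pio.read_vcf(inputs["vcf"])
    if has("counts") and has("samples"):
        counts = pio.read_counts_tsv(inputs["counts"])
        samples = pio.read_sample_sheet(inputs["samples"])
        if has("gene_lengths"):
            lengths = pio.read_gene_lengths_tsv(inputs["gene_lengths"])
        elif "genes" in data:
            lengths = pd.Series(
                {
                    r.gene_id: sum(e - s for s, e in r.exons[0])
                    for r in data["genes"].itertuples()
                }
            )
        else:
            raise InputError("counts given but no gene lengths (gene_lengths or genes_gff)")
        data["expression"] = ex.ExpressionMatrix(
            counts=counts, lengths=lengths.reindex(counts.index), samples=samples
        )
    if has("divergence"):
        data["divergence"] = dv.validate_divergence_table(
            pio.read_divergence_tsv(inputs["divergence"])
        )
    if has("te_bed"):
        data["te"] = pio.read_bed(inputs["te_bed"])
    if has("regions_bed"):
        data["regions"] = pio.read_bed(inputs["regions_bed"])
    if has("cds_fasta"):
        data["cds"] = pio.read_fasta(inputs["cds_fasta"])

    declared = set()
    if "regions" in data:
        declared = set(data["regions"]["chrom"])
    if declared:
        for key in ("depth_female", "depth_male", "te"):
            if key in data:
                unknown = set(data[key]["chrom"]) - declared
                if unknown:
                    raise InputError(f"{key}: unknown chromosomes {sorted(unknown)}")
    return data


def _stage_seed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2**31))


def _gene_region_class(chrom: str, start: int, annotation: Optional[rg.RegionAnnotation]) -> str:
    if chrom != Z_CHROM:
        return classify_chromosome(chrom)
    if annotation is None or annotation.boundary_bp is None:
        return cfg.PAR
    lo, hi = annotation.dr_interval
    return cfg.DR if lo <= start < hi else cfg.PAR


# ---------------------------------------------------------------------------
# stages


def run_region_stage(data: dict, ac: AnalysisConfig) -> dict:
    if "depth_female" not in data:
        return {"status": "not run", "reason": "no female depth track"}
    gc = data.get("gc_track")
    tracks = rg.depth_windows_by_chromosome(
        data["depth_female"], ac.window_size, ac.min_covered, gc
    )
    if Z_CHROM not in tracks:
        raise InputError(f"no depth windows for {Z_CHROM}")
    autosomes = [t for name, t in tracks.items() if name != Z_CHROM]
    z_norm = rg.normalize_depth(tracks[Z_CHROM], autosomes, gc_correct=ac.gc_correct)
    ann = rg.infer_boundary_from_coverage(z_norm)

    result = {"status": "ok", "coverage": ann.to_dict()}

    if "expression" in data and "genes" in data:
        try:
            matrix = data["expression"]
            genes = data["genes"]
            z_genes = genes[genes["chrom"] == Z_CHROM].sort_values("start")
            expr = ex.normalized_expression(matrix)
            ratios = ex.mf_log2_ratios(expr, matrix.samples)
            sub = z_genes[z_genes["gene_id"].isin(ratios.index)]
            gr = pd.DataFrame(
                {
                    "start": sub["start"].to_numpy(),
                    "end": sub["end"].to_numpy(),
                    "ratio": (2.0 ** ratios.reindex(sub["gene_id"]).to_numpy()),
                }
            )
            windows = rg.compute_mf_expression_windows(gr, ac.mf_window_genes)
            e_ann = rg.infer_boundary_from_expression(windows)
            result["expression"] = e_ann.to_dict()
            if ann.boundary_bp is not None and e_ann.boundary_bp is not None:
                agree = abs(ann.boundary_bp - e_ann.boundary_bp) <= 2 * ac.window_size + (
                    int(gr["end"].max() - gr["start"].min()) // max(len(windows), 1)
                )
                result["methods_agree"] = bool(agree)
        except InputError as exc:
            result["expression"] = {"status": "not run", "reason": str(exc)}

    if "variants" in data and ann.boundary_bp is not None:
        z_len = int(max(ann.par_interval[1], ann.dr_interval[1]))
        track = rg.snp_density_track(
            data["variants"], ac.window_size, chrom=Z_CHROM, chrom_length=z_len
        )
        verified = rg.verify_boundary_with_snps(ann, track)
        result["coverage"] = verified.to_dict()
    elif "variants" not in data:
        result["snp_verification"] = {"status": "not run", "reason": "no VCF"}
    result["annotation"] = result["coverage"]
    return result


def run_expression_stage(data: dict, ac: AnalysisConfig, annotation, seed: int) -> dict:
    if "expression" not in data:
        return {"status": "not run", "reason": "no counts/samples"}
    matrix: ex.ExpressionMatrix = data["expression"]
    if "genes" in data:
        genes = data["genes"]
        region = pd.Series(
            [
                _gene_region_class(r.chrom, r.start, annotation)
                for r in genes.itertuples()
            ],
            index=genes["gene_id"].to_numpy(),
        )
        matrix.region_class = region.reindex(matrix.counts.index).fillna(cfg.OTHER)
    expr = ex.normalized_expression(matrix)
    ratios = ex.mf_log2_ratios(expr, matrix.samples)
    dosage = ex.dosage_summary(
        ratios, matrix.region_class if matrix.region_class is not None else pd.Series(dtype=object)
    )
    out = {"status": "ok", "dosage": dosage}

    n_m = len(matrix.sex_columns("M"))
    n_f = len(matrix.sex_columns("F"))
    if n_m >= 2 and n_f >= 2:
        calls = ex.call_sex_biased(matrix, fdr=ac.fdr)
        counts = calls.groupby("region_class")["call"].value_counts().unstack(fill_value=0)
        out["sex_bias_counts"] = {
            str(k): {str(c): int(v) for c, v in row.items()} for k, row in counts.iterrows()
        }
        out["enrichment"] = [
            ex.par_enrichment_test(calls, region, bias)
            for region in ("PAR", "DR", "Z")
            for bias in ("male", "female")
        ]
    else:
        out["sex_bias"] = {"status": "not run", "reason": "<2 replicates per sex"}
    return out


def run_divergence_stage(data: dict, ac: AnalysisConfig, annotation, seed: int) -> dict:
    if "divergence" not in data:
        return {"status": "not run", "reason": "no divergence table"}
    records = data["divergence"]
    boundary = annotation.boundary_bp if annotation is not None else None
    report = dv.faster_z_report(
        records,
        reference_classes=[classify_chromosome(c) for c in ac.reference_chromosomes],
        n_boot=ac.n_boot,
        n_perm=ac.n_perm,
        seed=seed,
        alpha=ac.alpha,
        max_total_subs=ac.max_total_subs,
        boundary_bp=boundary if ac.boundary_exclusion_bp > 0 else None,
        boundary_exclusion_bp=ac.boundary_exclusion_bp,
    )
    out = {
        "status": "ok",
        "rates": {k: v.to_dict() for k, v in report["rates"].items()},
        "comparisons": [c.to_dict() for c in report["comparisons"]],
        "n_outliers_removed": report["n_outliers_removed"],
    }
    if "boundary_robustness" in report:
        br = report["boundary_robustness"]
        out["boundary_robustness"] = {
            "rates": {k: v.to_dict() for k, v in br["rates"].items()},
            "comparisons": [c.to_dict() for c in br["comparisons"]],
            "n_genes_excluded": br["n_genes_excluded"],
        }
    return out


def run_feature_stage(data: dict, ac: AnalysisConfig, annotation) -> dict:
    if "genes" not in data:
        return {"status": "not run", "reason": "no gene models"}
    genes = data["genes"]
    gene_class = pd.Series(
        [_gene_region_class(r.chrom, r.start, annotation) for r in genes.itertuples()],
        index=genes["gene_id"].to_numpy(),
    )
    out: dict = {"status": "ok", "per_class": {}, "tests": [], "size_correlations": {}}
    per_gene: Dict[str, pd.Series] = {}

    models = {r.gene_id: r.exons for r in genes.itertuples()}
    introns = ft.intron_sizes(models)
    intron_series = pd.Series(
        {g: float(np.mean(v)) for g, v in introns.items() if v}, dtype=float
    )
    per_gene["intron_size"] = intron_series

    if "cds" in data:
        gc3_vals, enc_vals = {}, {}
        for gene_id, seq in data["cds"].items():
            try:
                c = ft.CodingSequence(gene_id, seq)
                gc3_vals[gene_id] = ft.gc3s(c)
                enc_vals[gene_id] = ft.enc(c, use_background=False)
            except Exception:  # genes with no estimable codons are skipped
                continue
        per_gene["gc3s"] = pd.Series(gc3_vals, dtype=float)
        per_gene["enc"] = pd.Series(enc_vals, dtype=float)

    window_feats: Dict[str, Dict[str, np.ndarray]] = {}
    chrom_sizes: Dict[str, int] = {}
    if "regions" in data:
        for chrom, sub in data["regions"].groupby("chrom"):
            chrom_sizes[str(chrom)] = int(sub["end"].max())
    if "te" in data and chrom_sizes:
        for chrom, size in chrom_sizes.items():
            starts = np.arange(0, size, ac.window_size, dtype=np.int64)
            grid = pd.DataFrame(
                {"start": starts, "end": np.minimum(starts + ac.window_size, size)}
            )
            te_sub = data["te"][data["te"]["chrom"] == chrom]
            window_feats.setdefault("te_density", {})[chrom] = ft.interval_density_windows(
                te_sub[["start", "end"]], grid
            )
            exon_rows = []
            for r in genes[genes["chrom"] == chrom].itertuples():
                for t in r.exons[:1]:
                    exon_rows.extend(t)
            if exon_rows:
                exon_df = pd.DataFrame(exon_rows, columns=["start", "end"])
                window_feats.setdefault("exon_density", {})[chrom] = (
                    ft.interval_density_windows(exon_df, grid)
                )

    def window_class(chrom: str, size: int) -> np.ndarray:
        starts = np.arange(0, size, ac.window_size, dtype=np.int64)
        mids = starts + ac.window_size // 2
        return np.array([_gene_region_class(chrom, int(m), annotation) for m in mids])

    ref_classes = [classify_chromosome(c) for c in ac.reference_chromosomes]
    for feat, series in per_gene.items():
        klass = gene_class.reindex(series.index)
        for region in (cfg.PAR, cfg.DR):
            x = series[klass == region].dropna()
            y = series[klass.isin(ref_classes)].dropna()
            if len(x) >= 2 and len(y) >= 2:
                res = ft.region_feature_test(
                    x, y, feature=feat, region_class=region,
                    reference_class="+".join(ref_classes),
                )
                out["tests"].append(res.to_dict())
        out["per_class"].setdefault(feat, {})
        for region, vals in series.groupby(klass):
            out["per_class"][feat][str(region)] = {
                "median": float(np.median(vals)),
                "n": int(len(vals)),
            }

    for feat, by_chrom in window_feats.items():
        values = {}
        for chrom, dens in by_chrom.items():
            wc = window_class(chrom, chrom_sizes[chrom])
            for region in np.unique(wc):
                values.setdefault(str(region), []).append(dens[wc == region])
        out["per_class"].setdefault(feat, {})
        for region, chunks in values.items():
            allv = np.concatenate(chunks)
            out["per_class"][feat][region] = {
                "median": float(np.median(allv)),
                "n": int(allv.size),
            }
        ref_chunks = [np.concatenate(values[r]) for r in values if r in ref_classes]
        ref_vals = np.concatenate(ref_chunks) if ref_chunks else np.array([])
        for region in (cfg.PAR, cfg.DR):
            if region in values and ref_vals.size >= 2:
                res = ft.region_feature_test(
                    np.concatenate(values[region]),
                    ref_vals,
                    feature=feat,
                    region_class=region,
                    reference_class="+".join(ref_classes),
                )
                out["tests"].append(res.to_dict())
        if len(by_chrom) >= 3:
            summaries = [
                (chrom_sizes[chrom], float(np.mean(dens))) for chrom, dens in sorted(by_chrom.items())
            ]
            r, p = ft.chromosome_size_correlation(summaries)
            out["size_correlations"][feat] = {"r": r, "p": p, "n": len(summaries)}
    return out


# ---------------------------------------------------------------------------


def run_pipeline(pconfig: PipelineConfig) -> dict:
    """Run all stages and return the analysis report (a JSON-ready dict)."""
    pio.ensure_dir(pconfig.outdir)
    if pconfig.simulation is not None and not pconfig.inputs:
        simdir = os.path.join(pconfig.outdir, "simulated_inputs")
        sim_config = pconfig.simulation
        paths = write_bundle(sim_config, simdir)
        pconfig.inputs = {k: v for k, v in paths.items() if k != "truth"}

    data = parse_inputs(pconfig)
    ac = pconfig.analysis

    report: dict = {
        "provenance": {
            "package": "parzev",
            "config_hash": pconfig.config_hash(),
            "seed": pconfig.seed,
            "stage_seeds": {
                "divergence": _stage_seed(pconfig.seed, 1),
                "expression": _stage_seed(pconfig.seed, 2),
            },
            "inputs": {
                k: pio.sha256_file(v)
                for k, v in sorted(pconfig.inputs.items())
                if v and os.path.exists(v)
            },
        }
    }

    region_result = run_region_stage(data, ac)
    report["regions"] = region_result
    annotation = None
    if region_result.get("annotation"):
        d = region_result["annotation"]
        if d.get("boundary_bp") is not None:
            annotation = rg.RegionAnnotation(
                chromosome=d["chromosome"],
                boundary_bp=d["boundary_bp"],
                par_interval=tuple(d["par_interval"]),
                dr_interval=tuple(d["dr_interval"]),
                method=d["method"],
            )

    report["expression"] = run_expression_stage(
        data, ac, annotation, report["provenance"]["stage_seeds"]["expression"]
    )
    report["divergence"] = run_divergence_stage(
        data, ac, annotation, report["provenance"]["stage_seeds"]["divergence"]
    )
    report["features"] = run_feature_stage(data, ac, annotation)
    return report


def save_report(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=2)
        fh.write("\n")


def significance_stars(p: Optional[float]) -> str:
    """Star coding used in the rendered tables: *<0.05, **<0.01, ***<0.001."""
    if p is None or not np.isfinite(p):
        return "NA"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def render_report(report: dict) -> str:
    """Human-readable summary of an analysis report."""
    lines = []
    lines.append("parzev analysis report")
    lines.append(f"config hash: {report['provenance']['config_hash'][:12]}")
    lines.append("")

    reg = report.get("regions", {})
    if reg.get("status") == "ok":
        ann = reg["annotation"]
        if ann["boundary_bp"] is not None:
            lines.append(
                f"PAR/DR boundary ({ann['method']}): {ann['boundary_bp']:,} bp "
                f"(DR mean depth ratio {ann['dr_mean_ratio']:.3f}; flags: "
                f"{', '.join(ann['flags']) or 'none'})"
            )
        else:
            lines.append("no DR detected on the Z chromosome")
    else:
        lines.append(f"regions: {reg.get('status', 'not run')}")
    lines.append("")

    div = report.get("divergence", {})
    if div.get("status") == "ok":
        lines.append("rates (dN, dS, omega with 95% bootstrap CI):")
        for name, r in div["rates"].items():
            om = "NA" if r["omega"] is None else f"{r['omega']:.4f}"
            ci = r.get("ci_omega")
            ci_txt = f" [{ci[0]:.4f}, {ci[1]:.4f}]" if ci else ""
            lines.append(
                f"  {name:>10}: dN={r['dn']:.5f} dS={r['ds']:.5f} omega={om}{ci_txt} "
                f"(n={r['n_genes']})"
            )
        lines.append("contrasts vs autosomal reference (two-sided permutation):")
        for c in div["comparisons"]:
            stars = significance_stars(c["p_value"])
            lines.append(
                f"  {c['region_class']:>4} {c['statistic_name']:>5}: "
                f"diff={c['observed_difference']:+.5f} p={c['p_value']:.4g} "
                f"{stars or 'ns'} ({c['direction']})"
            )
    else:
        lines.append(f"divergence: {div.get('status', 'not run')}")
    lines.append("")

    expr = report.get("expression", {})
    if expr.get("status") == "ok":
        dosage = expr["dosage"]
        lines.append("dosage compensation (log2 M/F by region class):")
        for klass, s in dosage["classes"].items():
            lines.append(
                f"  {klass:>10}: median log2={s['median_log2']:+.3f} "
                f"(M/F {s['median_ratio']:.2f}, n={s['n']})"
            )
        lines.append(
            "  partial dosage compensation in DR: "
            + ("yes" if dosage["partial_compensation_dr"] else "no")
        )
        for t in expr.get("enrichment", []):
            stars = significance_stars(t["p_value"])
            orr = "NA" if not np.isfinite(t["odds_ratio"]) else f"{t['odds_ratio']:.2f}"
            lines.append(
                f"  {t['region']:>4} {t['bias']}-biased enrichment: OR={orr} "
                f"p={t['p_value']:.4g} {stars or 'ns'}"
            )
    else:
        lines.append(f"expression: {expr.get('status', 'not run')}")
    lines.append("")

    feats = report.get("features", {})
    if feats.get("status") == "ok":
        lines.append("genomic-feature contrasts (Wilcoxon rank-sum vs reference):")
        for t in feats["tests"]:
            stars = significance_stars(t["p_value"])
            med = t.get("medians")
            med_txt = f" medians {med[0]:.4g} vs {med[1]:.4g}" if med else ""
            lines.append(
                f"  {t['region_class']:>4} {t['statistic_name']:>12}:{med_txt} "
                f"p={t['p_value']:.4g} {stars or 'ns'}"
            )
        for feat, c in feats.get("size_correlations", {}).items():
            lines.append(
                f"  chromosome size vs {feat}: r={c['r']:+.3f} p={c['p']:.3g} (n={c['n']})"
            )
    else:
        lines.append(f"features: {feats.get('status', 'not run')}")
    return "\n".join(lines) + "\n"
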