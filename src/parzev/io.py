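"""Format readers and writers.

Conventions: bedGraph/BED are 0-based half-open and pass through unchanged;
GFF3 (1-based inclusive) and VCF (1-based positions) are converted to the
internal 0-based half-open convention at the I/O edge, and converted back
when writing — the conversions are involutive.  Strand is recorded but
coordinates are never strand-flipped.  All writers produce plain text with
fixed float formatting so identical inputs serialize byte-identically.
"""

from __future__ import annotations

import logging
import os
from typing import Dict, Iterable, List, Optional

import gffutils
import numpy as np
import pandas as pd
import pysam

from .errors import InputError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# bedGraph / BED


def read_bedgraph(path: str) -> pd.DataFrame:
    """bedGraph -> DataFrame(chrom, start, end, depth); 0-based half-open."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "depth"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "depth": float},
    )
    _check_intervals(df, path)
    return df


def write_bedgraph(df: pd.DataFrame, path: str, value_col: str = "depth") -> None:
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{getattr(row, value_col):.6g}\n"
            )


def read_bed(path: str) -> pd.DataFrame:
    """BED3(+name) -> DataFrame(chrom, start, end[, name]); 0-based half-open."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    _check_intervals(df, path)
    return df


def write_bed(df: pd.DataFrame, path: str) -> None:
    cols = [c for c in ("chrom", "start", "end", "name") if c in df.columns]
    with open(path, "w") as fh:
        for row in df[cols].itertuples(index=False):
            fields = [str(row.chrom), str(int(row.start)), str(int(row.end))]
            if "name" in cols:
                fields.append(str(row.name))
            fh.write("\t".join(fields) + "\n")


def write_region_annotation_bed(annotation, path: str) -> None:
    """Serialize a RegionAnnotation's class intervals as BED4."""
    rows = []
    if annotation.par_interval is not None:
        rows.append((annotation.chromosome, *annotation.par_interval, "PAR"))
    if annotation.dr_interval is not None:
        rows.append((annotation.chromosome, *annotation.dr_interval, "DR"))
    rows.sort(key=lambda r: r[1])
    write_bed(pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]), path)


def _check_intervals(df: pd.DataFrame, path: str) -> None:
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        raise InputError(f"{path}: end <= start at line(s) {list(bad[:5] + 1)}")


def read_repeatmasker_out(path: str) -> pd.DataFrame:
    """RepeatMasker .out -> DataFrame(chrom, start, end, family).

    Coordinates in .out files are 1-based inclusive; converted to 0-based
    half-open here.
    """
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.split()
            if len(parts) < 11 or not parts[0].isdigit():
                continue  # header / separator lines
            chrom, start, end, family = parts[4], int(parts[5]), int(parts[6]), parts[10]
            rows.append((chrom, start - 1, end, family))
    if not rows:
        raise InputError(f"{path}: no RepeatMasker alignments found")
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "family"])


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(genes: Iterable, path: str) -> None:
    """Serialize Gene objects (0-based half-open) as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chromosome}\tparzev\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chromosome}\tparzev\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for j, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chromosome}\tparzev\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.exon{j};Parent={mrna_id}\n"
                )


def read_gff3_genes(path: str) -> pd.DataFrame:
    """GFF3 -> one row per gene: gene_id, chrom, start, end, strand, exons.

    ``exons`` is a list of transcripts, each a sorted list of (start, end)
    0-based half-open tuples.  Duplicate gene IDs raise.
    """
    db = gffutils.create_db(
        path,
        ":memory:",
        merge_strategy="error",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    rows = []
    seen = set()
    for gene in db.features_of_type("gene"):
        if gene.id in seen:
            raise InputError(f"duplicated gene ID {gene.id}")
        seen.add(gene.id)
        transcripts = []
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = sorted(
                (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
            )
            if exons:
                transcripts.append(exons)
        if not transcripts:
            exons = sorted((f.start - 1, f.end) for f in db.children(gene, featuretype="exon"))
            if exons:
                transcripts.append(exons)
        rows.append(
            {
                "gene_id": gene.id,
                "chrom": gene.seqid,
                "start": gene.start - 1,
                "end": gene.end,
                "strand": gene.strand,
                "exons": transcripts,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# VCF


def write_vcf(variants: pd.DataFrame, path: str, contigs: Optional[Dict[str, int]] = None) -> None:
    """Write (chrom, pos 0-based, af) as a minimal VCF (1-based positions)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">\n')
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={int(length)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in variants.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{int(row.pos) + 1}\t.\tA\tG\t.\tPASS\tAF={row.af:.4f}\n"
            )


def read_vcf(path: str) -> pd.DataFrame:
    """VCF -> DataFrame(chrom, pos 0-based, af) using the AF INFO field."""
    vf = pysam.VariantFile(path)
    rows = []
    for rec in vf.fetch() if vf.index is not None else vf:
        af = rec.info.get("AF")
        if af is None:
            af = np.nan
        elif isinstance(af, (tuple, list)):
            af = af[0]
        rows.append((rec.chrom, rec.pos - 1, float(af)))
    return pd.DataFrame(rows, columns=["chrom", "pos", "af"])


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(seqs: Dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_fasta(path: str) -> Dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


# ---------------------------------------------------------------------------
# TSV tables


def write_divergence_tsv(df: pd.DataFrame, path: str) -> None:
    cols = [
        "gene_id",
        "chromosome",
        "region_class",
        "start",
        "n_sites",
        "s_sites",
        "n_subs",
        "s_subs",
        "dn",
        "ds",
    ]
    cols = [c for c in cols if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_divergence_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "region_class", "n_sites", "s_sites", "n_subs", "s_subs"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_counts_tsv(counts: pd.DataFrame, path: str) -> None:
    out = counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.8g")


def read_counts_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_sample_sheet(samples: pd.DataFrame, path: str) -> None:
    out = samples.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_sample_sheet(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    if "sex" not in df.columns:
        raise InputError(f"{path}: sample sheet needs a 'sex' column")
    return df


def write_gene_lengths_tsv(lengths: pd.Series, path: str) -> None:
    out = lengths.rename("length").to_frame()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_gene_lengths_tsv(path: str) -> pd.Series:
    return pd.read_csv(path, sep="\t", index_col="gene_id")["length"]


# ---------------------------------------------------------------------------


def windowtrack_to_bedgraph_df(track) -> pd.DataFrame:
    w = track.windows
    return pd.DataFrame(
        {
            "chrom": track.chromosome,
            "start": w["start"],
            "end": w["end"],
            "depth": w["mean_depth"],
        }
    )


def sha256_file(path: str) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
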