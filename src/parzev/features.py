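"""Efficacy-of-selection proxies: GC3s, ENC, interval densities, intron sizes.

Codon-usage bias (ENC, lower = stronger bias), third-position GC at
synonymous sites (GC3s, a proxy for GC-biased gene conversion and hence
recombination rate), transposable-element and exon densities in fixed
windows, and intron sizes are all indirect markers of how effectively
selection operates in a genomic region.  Region-versus-autosome contrasts
use the two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

from .divergence import ComparisonResult
from .errors import InputError, UndefinedValueError

log = logging.getLogger(__name__)

ENC_MIN, ENC_MAX = 20.0, 61.0

_table = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_table.stop_codons)

#: amino acid -> tuple of sense codons (6-fold families kept whole)
SYN_FAMILIES: Dict[str, tuple] = {}
for _codon, _aa in _table.forward_table.items():
    SYN_FAMILIES.setdefault(_aa, [])
    SYN_FAMILIES[_aa].append(_codon)
SYN_FAMILIES = {aa: tuple(sorted(c)) for aa, c in SYN_FAMILIES.items()}

#: Wright's degeneracy classes: size -> number of families (9/1/5/3)
FAMILY_CLASS_COUNTS = {2: 9, 3: 1, 4: 5, 6: 3}
_CLASS_ORDER = (2, 3, 4, 6)


@dataclass
class CodingSequence:
    """An in-frame CDS, optionally with intron-derived background frequencies."""

    gene_id: str
    cds: str
    background_freqs: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        self.cds = self.cds.upper()
        if len(self.cds) % 3 != 0:
            raise InputError(f"{self.gene_id}: CDS length {len(self.cds)} not divisible by 3")
        bad = set(self.cds) - set("ACGTN")
        if bad:
            raise InputError(f"{self.gene_id}: invalid characters {sorted(bad)}")
        internal = [c for c in self.codons()[:-1] if c in STOP_CODONS]
        if internal:
            warnings.warn(f"{self.gene_id}: {len(internal)} internal stop codon(s)", stacklevel=2)

    def codons(self) -> list:
        return [self.cds[i : i + 3] for i in range(0, len(self.cds), 3)]


def _clean_codons(cds: CodingSequence) -> list:
    return [c for c in cds.codons() if "N" not in c]


def gc3s(cds: CodingSequence) -> float:
    """GC fraction at synonymous third codon positions (codonW convention).

    Only codons from synonymous families count: Met, Trp, and stop codons
    are excluded, as are codons containing N.
    """
    syn_codons = [
        c
        for c in _clean_codons(cds)
        if c not in STOP_CODONS and len(SYN_FAMILIES[_table.forward_table[c]]) > 1
    ]
    if not syn_codons:
        raise UndefinedValueError(f"{cds.gene_id}: no synonymous-family codons")
    gc = sum(1 for c in syn_codons if c[2] in "GC")
    return gc / len(syn_codons)


def _family_homozygosity(counts: np.ndarray, background: Optional[np.ndarray]) -> Optional[float]:
    """F (or background-corrected F') for one synonymous family.

    ``counts`` are codon counts within the family; ``background`` the
    expected within-family codon frequencies (None for the uncorrected
    estimator).  Returns None when the family is not estimable (n < 2 or a
    non-positive homozygosity).
    """
    n = counts.sum()
    if n < 2:
        return None
    p = counts / n
    m = counts.size
    if background is None:
        f = (n * np.sum(p**2) - 1.0) / (n - 1.0)
    else:
        chi2 = n * np.sum((p - background) ** 2 / background)
        f = (chi2 + n - m) / (m * (n - 1.0))
    return float(f) if f > 0 else None


def _background_family_freqs(codons: Sequence[str], freqs: Dict[str, float]) -> np.ndarray:
    w = np.array(
        [freqs.get(c[0], 0.25) * freqs.get(c[1], 0.25) * freqs.get(c[2], 0.25) for c in codons]
    )
    s = w.sum()
    if s <= 0:
        raise InputError("background frequencies sum to zero for a codon family")
    return w / s


def enc(cds: CodingSequence, use_background: bool = False) -> float:
    """Effective number of codons (Wright's statistic, range 20-61).

    ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, where Fk is the mean codon
    homozygosity of the k-fold degenerate families.  With ``use_background``
    the homozygosity is replaced by a chi-square deviation from codon
    frequencies expected under the gene's background (intron) nucleotide
    composition, removing the contribution of local base composition to
    apparent bias.  Degeneracy classes with no estimable family borrow the
    mean of the nearest estimable classes; the result is clamped to
    [20, 61].
    """
    if use_background and not cds.background_freqs:
        raise InputError(f"{cds.gene_id}: background frequencies required")
    codon_list = [c for c in _clean_codons(cds) if c not in STOP_CODONS]
    if not codon_list:
        raise UndefinedValueError(f"{cds.gene_id}: no sense codons")
    counts = pd.Series(codon_list).value_counts()

    class_fs: Dict[int, list] = {k: [] for k in FAMILY_CLASS_COUNTS}
    for aa, fam in SYN_FAMILIES.items():
        size = len(fam)
        if size == 1:
            continue
        fam_counts = np.array([counts.get(c, 0) for c in fam], dtype=float)
        background = (
            _background_family_freqs(fam, cds.background_freqs) if use_background else None
        )
        f = _family_homozygosity(fam_counts, background)
        if f is not None:
            class_fs[size].append(f)

    mean_f: Dict[int, float] = {
        k: float(np.mean(v)) for k, v in class_fs.items() if len(v) > 0
    }
    if not mean_f:
        raise UndefinedValueError(f"{cds.gene_id}: no estimable codon family")
    for k in _CLASS_ORDER:
        if k not in mean_f:
            order = [c for c in _CLASS_ORDER if c in mean_f]
            below = [c for c in order if c < k]
            above = [c for c in order if c > k]
            neighbors = ([below[-1]] if below else []) + ([above[0]] if above else [])
            mean_f[k] = float(np.mean([mean_f[c] for c in neighbors]))

    value = 2.0 + sum(FAMILY_CLASS_COUNTS[k] / mean_f[k] for k in _CLASS_ORDER)
    return float(np.clip(value, ENC_MIN, ENC_MAX))


def nucleotide_freqs(seq: str) -> Dict[str, float]:
    """Composition of a background (intron) sequence, ignoring N."""
    seq = seq.upper()
    tot = sum(seq.count(b) for b in "ACGT")
    if tot == 0:
        raise InputError("background sequence has no unambiguous bases")
    return {b: seq.count(b) / tot for b in "ACGT"}


# ---------------------------------------------------------------------------
# interval densities


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Union of possibly overlapping start/end intervals (0-based half-open)."""
    if len(intervals) == 0:
        return pd.DataFrame({"start": [], "end": []}, dtype=np.int64)
    df = intervals.sort_values("start", kind="stable")
    starts = df["start"].to_numpy(dtype=np.int64)
    ends = df["end"].to_numpy(dtype=np.int64)
    if np.any(ends <= starts):
        raise InputError("interval end must exceed start")
    m_start, m_end = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= m_end[-1]:
            m_end[-1] = max(m_end[-1], e)
        else:
            m_start.append(s)
            m_end.append(e)
    return pd.DataFrame({"start": m_start, "end": m_end})


def interval_density_windows(intervals: pd.DataFrame, windows: pd.DataFrame) -> np.ndarray:
    """Fraction of each window covered by the merged intervals.

    ``windows`` needs start/end columns (a WindowTrack grid).  Overlapping
    input intervals are merged first, so duplicated annotations do not
    inflate the density; an interval straddling a window edge contributes
    only its overlapping bp to each side.
    """
    merged = merge_intervals(intervals)
    ms = merged["start"].to_numpy(dtype=np.int64)
    me = merged["end"].to_numpy(dtype=np.int64)
    lengths = me - ms
    prefix = np.concatenate([[0], np.cumsum(lengths)])

    def covered_up_to(x: np.ndarray) -> np.ndarray:
        j = np.searchsorted(ms, x, side="right") - 1
        base = prefix[np.maximum(j + 1, 0)]
        inside = np.where(
            (j >= 0) & (x < me[np.maximum(j, 0)]), me[np.maximum(j, 0)] - x, 0
        )
        return base - inside

    ws = windows["start"].to_numpy(dtype=np.int64)
    we = windows["end"].to_numpy(dtype=np.int64)
    if len(ms) == 0:
        return np.zeros(len(ws))
    cov = covered_up_to(we) - covered_up_to(ws)
    return cov / (we - ws)


# ---------------------------------------------------------------------------
# intron sizes


def intron_sizes(gene_models: Dict[str, Sequence[Sequence[tuple]]]) -> Dict[str, list]:
    """Per-gene intron lengths from exon structures.

    ``gene_models`` maps gene_id to a list of transcripts, each a list of
    (start, end) exon intervals (0-based half-open, sorted, non-overlapping
    within a transcript).  For multi-transcript genes the transcript with the
    greatest total exon length is used.  Genes with overlapping exons are
    skipped with a warning.  Single-exon genes yield an empty list.
    """
    out: Dict[str, list] = {}
    for gene_id, transcripts in gene_models.items():
        if not transcripts:
            continue
        best = max(transcripts, key=lambda t: sum(e - s for s, e in t))
        exons = sorted(best)
        if any(exons[i][1] > exons[i + 1][0] for i in range(len(exons) - 1)):
            log.warning("gene %s has overlapping exons; skipped", gene_id)
            continue
        out[gene_id] = [exons[i + 1][0] - exons[i][1] for i in range(len(exons) - 1)]
    return out


# ---------------------------------------------------------------------------
# contrasts


def region_feature_test(
    values_region: Sequence[float],
    values_reference: Sequence[float],
    feature: str = "feature",
    region_class: str = "",
    reference_class: str = "",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum contrast of a feature between regions."""
    x = np.asarray(values_region, dtype=float)
    y = np.asarray(values_reference, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise InputError("both groups need at least 2 values")
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        p = 1.0  # all observations tied: no evidence either way
    else:
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    diff = float(np.median(x) - np.median(y))
    if p >= alpha or diff == 0:
        direction = "ns"
    else:
        direction = "faster" if diff > 0 else "slower"
    return ComparisonResult(
        region_class=region_class,
        reference_class=reference_class,
        statistic_name=feature,
        observed_difference=diff,
        p_value=p,
        n_permutations=0,
        direction=direction,
        n_region=int(x.size),
        n_reference=int(y.size),
        medians=(float(np.median(x)), float(np.median(y))),
    )


def chromosome_size_correlation(
    summaries: Sequence[tuple], method: str = "pearson"
) -> tuple:
    """Correlation of a per-chromosome feature with chromosome size.

    ``summaries`` is a sequence of (size_bp, feature_value); returns (r, p).
    """
    if len(summaries) < 3:
        raise InputError("need at least 3 chromosomes")
    size = np.array([s for s, _ in summaries], dtype=float)
    value = np.array([v for _, v in summaries], dtype=float)
    if np.std(size) == 0 or np.std(value) == 0:
        raise UndefinedValueError("zero variance in size or feature")
    if method == "pearson":
        r, p = stats.pearsonr(size, value)
    elif method == "spearman":
        r, p = stats.spearmanr(size, value)
    else:
        raise InputError(f"unknown correlation method {method!r}")
    return float(r), float(p)
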