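"""PAR/DR boundary inference from depth, expression, and SNP tracks.

In a female ZW bird, sequencing reads from the degenerate W no longer map to
the differentiated region (DR) of the Z, so female read depth drops to half
of the autosomal level there, female heterozygosity disappears, and without
global dosage compensation male/female expression rises above 1.  Each of
these signals yields an independent estimate of the PAR/DR boundary; this
module computes windowed tracks for all three and locates the transition
with a least-squares two-segment changepoint scan.

The changepoint operationalization: the boundary is the window start that
minimizes the summed within-segment squared error of the normalized track,
subject to acceptance bands on the segment means (DR ratio in
``dr_band``, PAR ratio in ``par_band``) and a minimum run length.  The
half-coverage "starts to appear" position is therefore reported at window
resolution, with the window width as its uncertainty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, InsufficientDataError

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 50_000
DEFAULT_MIN_COVERED = 5_000
DEFAULT_AF_BAND = (0.2, 0.8)
DEFAULT_DR_BAND = (0.35, 0.65)
DEFAULT_PAR_BAND = (0.8, 1.2)


@dataclass
class WindowTrack:
    """Fixed-width windowed summary of a per-base quantity on one chromosome.

    ``windows`` holds columns start, end (0-based half-open), mean_depth,
    covered_bases, gc_fraction (NaN when unknown) and, after
    :func:`normalize_depth`, normalized_ratio.
    """

    chromosome: str
    windows: pd.DataFrame

    def __post_init__(self) -> None:
        w = self.windows
        required = {"start", "end", "mean_depth", "covered_bases"}
        missing = required - set(w.columns)
        if missing:
            raise InputError(f"WindowTrack missing columns: {sorted(missing)}")
        if "gc_fraction" not in w.columns:
            w["gc_fraction"] = np.nan
        starts = w["start"].to_numpy()
        ends = w["end"].to_numpy()
        if len(w) and (np.any(ends <= starts) or np.any(np.diff(starts) <= 0)):
            raise InputError("windows must be sorted and non-overlapping")
        if len(w) and np.any(w["covered_bases"].to_numpy() > ends - starts):
            raise InputError("covered_bases exceeds window width")

    @property
    def has_ratio(self) -> bool:
        return "normalized_ratio" in self.windows.columns

    def __len__(self) -> int:
        return len(self.windows)


@dataclass
class RegionAnnotation:
    """PAR/DR assignment of one chromosome.

    ``boundary_bp`` is the transition position (start of the first window of
    the changed segment); None when no DR was detected.  Intervals are
    0-based half-open.  ``support`` counts windows per (PAR, DR) segment.
    """

    chromosome: str
    boundary_bp: Optional[int]
    par_interval: Optional[tuple]
    dr_interval: Optional[tuple]
    method: str  # coverage | expression | snp | projected
    dr_mean_ratio: Optional[float] = None
    support: tuple = (0, 0)
    flags: list = field(default_factory=list)
    window_size: Optional[int] = None

    @property
    def no_dr(self) -> bool:
        return self.dr_interval is None

    def to_dict(self) -> dict:
        return {
            "chromosome": self.chromosome,
            "boundary_bp": None if self.boundary_bp is None else int(self.boundary_bp),
            "par_interval": list(map(int, self.par_interval)) if self.par_interval else None,
            "dr_interval": list(map(int, self.dr_interval)) if self.dr_interval else None,
            "method": self.method,
            "dr_mean_ratio": None if self.dr_mean_ratio is None else float(self.dr_mean_ratio),
            "support": list(map(int, self.support)),
            "flags": list(self.flags),
            "window_size": None if self.window_size is None else int(self.window_size),
        }


# ---------------------------------------------------------------------------
# windowed depth


def _check_sorted_disjoint(start: np.ndarray, end: np.ndarray) -> None:
    if np.any(end <= start):
        raise InputError("interval end must exceed start")
    if len(start) > 1 and np.any(start[1:] < end[:-1]):
        raise InputError("depth intervals must be sorted and non-overlapping")


def compute_depth_windows(
    depth_intervals: pd.DataFrame,
    window_size: int = DEFAULT_WINDOW,
    min_covered: int = DEFAULT_MIN_COVERED,
    gc_intervals: Optional[pd.DataFrame] = None,
) -> WindowTrack:
    """Average interval depths into fixed windows for one chromosome.

    ``depth_intervals`` needs columns chrom/start/end/depth (bedGraph
    semantics, 0-based half-open) and must cover a single chromosome with
    sorted, non-overlapping intervals.  Windows whose covered span is below
    ``min_covered`` bp are dropped.  ``gc_intervals`` (chrom/start/end/gc)
    optionally attaches a length-weighted mean GC fraction per window.
    """
    if window_size <= 0:
        raise InputError("window_size must be positive")
    chroms = depth_intervals["chrom"].unique()
    if len(chroms) != 1:
        raise InputError(f"expected a single chromosome, got {list(chroms)}")
    chrom = str(chroms[0])
    start = depth_intervals["start"].to_numpy(dtype=np.int64)
    end = depth_intervals["end"].to_numpy(dtype=np.int64)
    depth = depth_intervals["depth"].to_numpy(dtype=float)
    _check_sorted_disjoint(start, end)

    n_win = int((end.max() + window_size - 1) // window_size)
    depth_sum = np.zeros(n_win)
    cover = np.zeros(n_win)
    _accumulate(start, end, depth, window_size, depth_sum, cover)

    win_start = np.arange(n_win, dtype=np.int64) * window_size
    win_end = win_start + window_size
    with np.errstate(invalid="ignore"):
        mean_depth = np.where(cover > 0, depth_sum / np.maximum(cover, 1), np.nan)

    gc = np.full(n_win, np.nan)
    if gc_intervals is not None and len(gc_intervals):
        g = gc_intervals[gc_intervals["chrom"] == chrom]
        gsum = np.zeros(n_win)
        gcov = np.zeros(n_win)
        _accumulate(
            g["start"].to_numpy(dtype=np.int64),
            g["end"].to_numpy(dtype=np.int64),
            g["gc"].to_numpy(dtype=float),
            window_size,
            gsum,
            gcov,
        )
        gc = np.where(gcov > 0, gsum / np.maximum(gcov, 1), np.nan)

    keep = cover >= min_covered
    n_dropped = int(np.sum(~keep & (cover > 0)))
    if n_dropped:
        log.info("%s: dropped %d windows with < %d covered bp", chrom, n_dropped, min_covered)
    df = pd.DataFrame(
        {
            "start": win_start[keep],
            "end": win_end[keep],
            "mean_depth": mean_depth[keep],
            "covered_bases": cover[keep].astype(np.int64),
            "gc_fraction": gc[keep],
        }
    ).reset_index(drop=True)
    return WindowTrack(chromosome=chrom, windows=df)


def _accumulate(
    start: np.ndarray,
    end: np.ndarray,
    value: np.ndarray,
    window_size: int,
    vsum: np.ndarray,
    cover: np.ndarray,
) -> None:
    """Distribute value-weighted interval bp onto a fixed window grid."""
    if len(start) == 0:
        return
    first = start // window_size
    last = (end - 1) // window_size
    counts = (last - first + 1).astype(np.int64)
    total = int(counts.sum())
    rep = np.repeat(np.arange(len(start)), counts)
    offsets = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    win = first[rep] + offsets
    ov_start = np.maximum(start[rep], win * window_size)
    ov_end = np.minimum(end[rep], (win + 1) * window_size)
    ov = (ov_end - ov_start).astype(float)
    np.add.at(vsum, win, value[rep] * ov)
    np.add.at(cover, win, ov)


def depth_windows_by_chromosome(
    depth_intervals: pd.DataFrame,
    window_size: int = DEFAULT_WINDOW,
    min_covered: int = DEFAULT_MIN_COVERED,
    gc_intervals: Optional[pd.DataFrame] = None,
) -> dict:
    """Apply :func:`compute_depth_windows` per chromosome of a bedGraph table."""
    out = {}
    for chrom, sub in depth_intervals.groupby("chrom", sort=True):
        out[str(chrom)] = compute_depth_windows(
            sub.reset_index(drop=True), window_size, min_covered, gc_intervals
        )
    return out


# ---------------------------------------------------------------------------
# normalization


def normalize_depth(
    z_track: WindowTrack,
    autosome_tracks: Sequence[WindowTrack],
    gc_correct: bool = False,
    gc_bin_width: float = 0.02,
) -> WindowTrack:
    """Attach normalized_ratio = window depth / autosomal median depth.

    With ``gc_correct`` each window's depth is instead divided by the median
    autosomal depth of its GC bin (bins of ``gc_bin_width``, pooled over all
    autosomal windows), which removes a linear or nonlinear GC-coverage
    trend; bins without autosomal windows fall back to the global median.
    """
    if not autosome_tracks:
        raise InputError("at least one autosome track is required")
    auto_depth = np.concatenate([t.windows["mean_depth"].to_numpy() for t in autosome_tracks])
    auto_depth = auto_depth[np.isfinite(auto_depth)]
    if auto_depth.size == 0:
        raise InputError("autosome tracks contain no finite depths")
    baseline = float(np.median(auto_depth))
    if baseline == 0:
        raise InputError("autosomal median depth is zero")

    w = z_track.windows.copy()
    depth = w["mean_depth"].to_numpy(dtype=float)
    if not gc_correct:
        ratio = depth / baseline
    else:
        auto_gc = np.concatenate([t.windows["gc_fraction"].to_numpy() for t in autosome_tracks])
        ok = np.isfinite(auto_gc)
        bins_auto = np.floor(auto_gc[ok] / gc_bin_width).astype(int)
        depths_auto = np.concatenate(
            [t.windows["mean_depth"].to_numpy() for t in autosome_tracks]
        )[ok]
        bin_median = {
            int(b): float(np.median(depths_auto[bins_auto == b])) for b in np.unique(bins_auto)
        }
        z_gc = w["gc_fraction"].to_numpy(dtype=float)
        denom = np.array(
            [
                bin_median.get(int(np.floor(g / gc_bin_width)), baseline)
                if np.isfinite(g)
                else baseline
                for g in z_gc
            ]
        )
        denom = np.where(denom > 0, denom, baseline)
        ratio = depth / denom
    w["normalized_ratio"] = ratio
    return WindowTrack(chromosome=z_track.chromosome, windows=w)


# ---------------------------------------------------------------------------
# changepoint scan


def two_segment_changepoint(values: np.ndarray, min_run: int = 1) -> tuple:
    """Best single split of a sequence by least squares.

    Returns (k, sse) where ``k`` splits values into [0, k) and [k, n), with
    ``min_run <= k <= n - min_run``, minimizing the summed within-segment
    squared error.  O(n) via cumulative sums; ties break to the smallest k.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2 * min_run:
        raise InsufficientDataError(f"need at least {2 * min_run} windows, got {n}")
    cs = np.concatenate([[0.0], np.cumsum(v)])
    cs2 = np.concatenate([[0.0], np.cumsum(v * v)])
    k = np.arange(min_run, n - min_run + 1)
    left_n = k.astype(float)
    right_n = (n - k).astype(float)
    left_sum = cs[k]
    right_sum = cs[n] - cs[k]
    sse = (cs2[k] - left_sum**2 / left_n) + (cs2[n] - cs2[k] - right_sum**2 / right_n)
    i = int(np.argmin(sse))
    return int(k[i]), float(sse[i])


def infer_boundary_from_coverage(
    track: WindowTrack,
    dr_band: tuple = DEFAULT_DR_BAND,
    par_band: tuple = DEFAULT_PAR_BAND,
    min_run: int = 10,
) -> RegionAnnotation:
    """Locate the PAR/DR boundary from normalized female depth ratios.

    The segment whose mean ratio is closer to 0.5 is labelled DR.  "No DR"
    (``dr_interval is None``) is returned when the putative DR mean falls
    outside ``dr_band`` or its run is shorter than ``min_run`` windows.  A
    PAR segment mean outside ``par_band`` adds a warning flag.
    """
    if not track.has_ratio:
        raise InputError("run normalize_depth first (normalized_ratio missing)")
    w = track.windows
    ratio = w["normalized_ratio"].to_numpy(dtype=float)
    k, _ = two_segment_changepoint(ratio, min_run=min_run)
    left_mean = float(np.mean(ratio[:k]))
    right_mean = float(np.mean(ratio[k:]))
    extent = (int(w["start"].iloc[0]), int(w["end"].iloc[-1]))
    boundary = int(w["start"].iloc[k])

    dr_is_right = abs(right_mean - 0.5) < abs(left_mean - 0.5)
    dr_mean = right_mean if dr_is_right else left_mean
    par_mean = left_mean if dr_is_right else right_mean
    dr_run = (len(w) - k) if dr_is_right else k

    flags = []
    if not (dr_band[0] <= dr_mean <= dr_band[1]) or dr_run < min_run:
        flags.append("no-DR")
        return RegionAnnotation(
            chromosome=track.chromosome,
            boundary_bp=None,
            par_interval=extent,
            dr_interval=None,
            method="coverage",
            dr_mean_ratio=None,
            support=(len(w), 0),
            flags=flags,
            window_size=int(w["end"].iloc[0] - w["start"].iloc[0]),
        )
    if not (par_band[0] <= par_mean <= par_band[1]):
        flags.append("par-ratio-out-of-band")
    if dr_is_right:
        par_iv, dr_iv = (extent[0], boundary), (boundary, extent[1])
        support = (k, len(w) - k)
    else:
        dr_iv, par_iv = (extent[0], boundary), (boundary, extent[1])
        support = (len(w) - k, k)
    return RegionAnnotation(
        chromosome=track.chromosome,
        boundary_bp=boundary,
        par_interval=par_iv,
        dr_interval=dr_iv,
        method="coverage",
        dr_mean_ratio=dr_mean,
        support=support,
        flags=flags,
        window_size=int(w["end"].iloc[0] - w["start"].iloc[0]),
    )


def segment_boundaries_recursive(
    values: np.ndarray, min_run: int = 10, max_depth: int = 3
) -> list:
    """Optional multi-boundary mode: recursive binary segmentation with BIC stop.

    Returns sorted split indices.  Intended for chromosomes that may carry a
    second PAR (kiwi-like); off by default in the pipeline.
    """
    v = np.asarray(values, dtype=float)

    def bic(seg_sse: float, n: int, n_params: int) -> float:
        var = max(seg_sse / n, 1e-12)
        return n * np.log(var) + n_params * np.log(n)

    def recurse(lo: int, hi: int, depth: int) -> list:
        n = hi - lo
        if depth >= max_depth or n < 2 * min_run:
            return []
        seg = v[lo:hi]
        sse0 = float(np.sum((seg - seg.mean()) ** 2))
        k, sse1 = two_segment_changepoint(seg, min_run=min_run)
        if bic(sse1, n, 2) + np.log(n) < bic(sse0, n, 1):
            return recurse(lo, lo + k, depth + 1) + [lo + k] + recurse(lo + k, hi, depth + 1)
        return []

    return sorted(recurse(0, v.size, 0))


# ---------------------------------------------------------------------------
# expression windows


def compute_mf_expression_windows(
    gene_ratios: pd.DataFrame, window_genes: int = 20
) -> pd.DataFrame:
    """Mean log2 male/female ratio in consecutive non-overlapping gene windows.

    ``gene_ratios`` needs columns start, end, ratio (>0), sorted by start.
    Returns one row per window with columns window, start (first gene start),
    end (last gene end), mean_log2, n_genes.  A trailing partial window is
    kept when it holds at least half of ``window_genes``.
    """
    if len(gene_ratios) == 0:
        raise InputError("empty gene list")
    g = gene_ratios
    starts = g["start"].to_numpy()
    if np.any(np.diff(starts) < 0):
        raise InputError("genes must be sorted by position")
    ratios = g["ratio"].to_numpy(dtype=float)
    if np.any(ratios <= 0):
        raise InputError("ratios must be > 0")
    ends = g["end"].to_numpy() if "end" in g.columns else starts
    log2r = np.log2(ratios)
    n = len(g)
    rows = []
    for i, lo in enumerate(range(0, n, window_genes)):
        hi = min(lo + window_genes, n)
        if hi - lo < window_genes and (hi - lo) < window_genes / 2:
            break
        rows.append(
            {
                "window": i,
                "start": int(starts[lo]),
                "end": int(ends[hi - 1]),
                "mean_log2": float(np.mean(log2r[lo:hi])),
                "n_genes": hi - lo,
            }
        )
    return pd.DataFrame(rows)


def infer_boundary_from_expression(
    windowed: pd.DataFrame, dr_min_log2: float = 0.2, min_run: int = 2
) -> RegionAnnotation:
    """Changepoint on windowed log2 M/F values; the higher segment is the DR.

    Requires the DR segment mean to reach ``dr_min_log2``, otherwise reports
    no DR.  ``boundary_bp`` is the start of the first gene in the first DR
    window.
    """
    if len(windowed) < 4:
        raise InsufficientDataError(f"need >= 4 expression windows, got {len(windowed)}")
    vals = windowed["mean_log2"].to_numpy(dtype=float)
    k, _ = two_segment_changepoint(vals, min_run=min_run)
    left_mean = float(np.mean(vals[:k]))
    right_mean = float(np.mean(vals[k:]))
    extent = (int(windowed["start"].iloc[0]), int(windowed["end"].iloc[-1]))
    dr_is_right = right_mean > left_mean
    dr_mean = right_mean if dr_is_right else left_mean
    if dr_mean < dr_min_log2:
        return RegionAnnotation(
            chromosome="",
            boundary_bp=None,
            par_interval=extent,
            dr_interval=None,
            method="expression",
            dr_mean_ratio=None,
            support=(len(windowed), 0),
            flags=["no-DR"],
        )
    if dr_is_right:
        boundary = int(windowed["start"].iloc[k])
        par_iv, dr_iv = (extent[0], boundary), (boundary, extent[1])
        support = (k, len(windowed) - k)
    else:
        boundary = int(windowed["start"].iloc[k])
        dr_iv, par_iv = (extent[0], boundary), (boundary, extent[1])
        support = (len(windowed) - k, k)
    return RegionAnnotation(
        chromosome="",
        boundary_bp=boundary,
        par_interval=par_iv,
        dr_interval=dr_iv,
        method="expression",
        dr_mean_ratio=float(2.0**dr_mean),
        support=support,
        flags=[],
    )


# ---------------------------------------------------------------------------
# SNP density


def snp_density_track(
    variants: pd.DataFrame,
    window_size: int = DEFAULT_WINDOW,
    af_band: tuple = DEFAULT_AF_BAND,
    chrom: Optional[str] = None,
    exons: Optional[pd.DataFrame] = None,
    chrom_length: Optional[int] = None,
) -> pd.DataFrame:
    """Heterozygous-SNP counts per fixed window.

    Variants need columns chrom, pos (0-based), af; only allele frequencies
    inside ``af_band`` (inclusive) are counted, mirroring a GATK-style
    heterozygote filter.  With ``exons`` (start/end intervals) the count is
    restricted to exonic variants and a density per exonic bp is added —
    the mode used when only RNA-seq variants are available.
    """
    v = variants
    if chrom is not None:
        v = v[v["chrom"] == chrom]
    af = v["af"].to_numpy(dtype=float)
    keep = (af >= af_band[0]) & (af <= af_band[1])
    pos = v["pos"].to_numpy(dtype=np.int64)[keep]

    exonic_bp = None
    if exons is not None:
        starts = exons["start"].to_numpy(dtype=np.int64)
        ends = exons["end"].to_numpy(dtype=np.int64)
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        m_start, m_end = _merge(starts, ends)
        in_exon = np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(m_start, pos, side="right") - 1
        ok = idx >= 0
        in_exon[ok] = pos[ok] < m_end[idx[ok]]
        pos = pos[in_exon]
        n_win = int(max(m_end.max() if len(m_end) else 0, pos.max() + 1 if len(pos) else 1) // window_size + 1)
        exonic_bp = np.zeros(n_win)
        dummy = np.zeros(n_win)
        _accumulate(m_start, m_end, np.ones(len(m_start)), window_size, dummy, exonic_bp)
    if len(pos) == 0:
        n_win = len(exonic_bp) if exonic_bp is not None else 0
    else:
        n_win = int(pos.max() // window_size + 1)
        if exonic_bp is not None and len(exonic_bp) > n_win:
            n_win = len(exonic_bp)
    if chrom_length is not None:
        # extend over variant-free tail so zero-count windows are explicit
        n_win = max(n_win, int((chrom_length + window_size - 1) // window_size))
    counts = np.bincount((pos // window_size).astype(int), minlength=n_win) if n_win else np.zeros(0, dtype=np.int64)
    win_start = np.arange(n_win, dtype=np.int64) * window_size
    out = pd.DataFrame({"start": win_start, "end": win_start + window_size, "count": counts})
    if exonic_bp is not None:
        bp = exonic_bp[:n_win] if len(exonic_bp) >= n_win else np.pad(exonic_bp, (0, n_win - len(exonic_bp)))
        out["exonic_bp"] = bp.astype(np.int64)
        with np.errstate(divide="ignore", invalid="ignore"):
            out["density"] = np.where(bp > 0, counts / np.maximum(bp, 1), np.nan)
    return out


def _merge(starts: np.ndarray, ends: np.ndarray) -> tuple:
    """Merge sorted, possibly overlapping intervals."""
    if len(starts) == 0:
        return starts, ends
    m_start, m_end = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= m_end[-1]:
            m_end[-1] = max(m_end[-1], e)
        else:
            m_start.append(s)
            m_end.append(e)
    return np.asarray(m_start), np.asarray(m_end)


def verify_boundary_with_snps(
    annotation: RegionAnnotation,
    density: pd.DataFrame,
    consistent_max: float = 0.05,
    ambiguous_min: float = 0.8,
) -> RegionAnnotation:
    """Cross-check a boundary against female heterozygous-SNP density.

    The DR should be devoid of female heterozygosity.  Flags added:
    "snp-consistent" when the DR median count is at most ``consistent_max``
    of the PAR median; "snp-elevated-DR" when it lies between
    ``consistent_max`` and ``ambiguous_min`` of the PAR median (the
    signature of degenerate W reads mismapping onto the Z); "snp-ambiguous"
    otherwise (including a flat track).
    """
    if annotation.boundary_bp is None or annotation.dr_interval is None:
        raise InputError("annotation has no boundary to verify")
    mid = (density["start"].to_numpy() + density["end"].to_numpy()) / 2.0
    dr_lo, dr_hi = annotation.dr_interval
    par_lo, par_hi = annotation.par_interval
    col = "density" if "density" in density.columns else "count"
    vals = density[col].to_numpy(dtype=float)
    in_dr = (mid >= dr_lo) & (mid < dr_hi)
    in_par = (mid >= par_lo) & (mid < par_hi)
    dr_med = float(np.nanmedian(vals[in_dr])) if in_dr.any() else np.nan
    par_med = float(np.nanmedian(vals[in_par])) if in_par.any() else np.nan

    flags = list(annotation.flags)
    if not np.isfinite(par_med) or par_med <= 0:
        flags.append("snp-ambiguous")
    else:
        frac = dr_med / par_med
        if frac <= consistent_max:
            flags.append("snp-consistent")
        elif frac < ambiguous_min:
            flags.append("snp-elevated-DR")
        else:
            flags.append("snp-ambiguous")
    return RegionAnnotation(
        chromosome=annotation.chromosome,
        boundary_bp=annotation.boundary_bp,
        par_interval=annotation.par_interval,
        dr_interval=annotation.dr_interval,
        method=annotation.method,
        dr_mean_ratio=annotation.dr_mean_ratio,
        support=annotation.support,
        flags=flags,
        window_size=annotation.window_size,
    )
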