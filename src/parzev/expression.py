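"""Dosage compensation and sex-biased-expression analysis.

Expression is carried as a genes x samples count matrix with per-gene
lengths and a sample sheet (sex, tissue, replicate).  Two normalizations are
available: TPM (per-sample, length- and depth-normalized) and
median-of-ratios size factors (the normalization used by standard
differential-expression tools), which is robust to library-composition
shifts — important here, because genes in the differentiated region are
systematically male-inflated and would otherwise drag every per-sample
scaling with them.  Dosage compensation is summarized as per-class medians
of log2 male/female ratios; sex-biased genes are called with a
negative-binomial Wald test (a documented simplified stand-in for a full DE
package; externally produced calls can be supplied instead) followed by
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from . import config as cfg

log = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Counts (genes x samples), gene lengths (bp), and sample metadata.

    ``samples`` is indexed by sample id with at least a ``sex`` column
    ('M'/'F'); ``region_class`` optionally assigns genes to PAR/DR/autosome
    classes.  ``true_sex_bias`` (simulation only) records the ground-truth
    fold-change per gene.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    samples: pd.DataFrame
    region_class: Optional[pd.Series] = None
    true_sex_bias: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise InputError("counts must be non-negative")
        if not self.counts.index.equals(self.lengths.index):
            self.lengths = self.lengths.reindex(self.counts.index)
            if self.lengths.isna().any():
                raise InputError("every gene needs a length")
        if "sex" not in self.samples.columns:
            raise InputError("sample sheet needs a 'sex' column")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise InputError(f"samples missing from sheet: {sorted(missing)}")
        bad_sex = set(self.samples["sex"]) - {"M", "F"}
        if bad_sex:
            raise InputError(f"sex labels must be M/F, got {sorted(bad_sex)}")

    @property
    def tpm(self) -> pd.DataFrame:
        return tpm_normalize(self.counts, self.lengths)

    def sex_columns(self, sex: str) -> list:
        return [s for s in self.counts.columns if self.samples.loc[s, "sex"] == sex]


@dataclass
class SexBiasCall:
    gene_id: str
    log2_fold_change: float
    p_value: float
    q_value: float
    call: str  # male-biased | female-biased | unbiased
    region_class: str = cfg.OTHER


# ---------------------------------------------------------------------------


def tpm_normalize(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: per sample, rate = count/length scaled to 1e6."""
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any():
        raise InputError("gene lengths must be positive")
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    if (totals == 0).any():
        zero = list(totals.index[totals == 0])
        raise InputError(f"all-zero samples: {zero}")
    return rate.div(totals, axis=1) * 1e6


def median_of_ratios_size_factors(
    counts: pd.DataFrame, reference_genes: Optional[pd.Index] = None
) -> pd.Series:
    """DESeq-style size factors: per-sample median ratio to the geometric-mean gene.

    ``reference_genes`` restricts the median to a subset of rows.  When the
    chromosome under study carries a global dosage effect (DR genes are
    male-inflated), estimating the factors from autosomal genes only keeps
    that signal out of the per-sample scaling.
    """
    if reference_genes is not None:
        ref = counts.index.intersection(reference_genes)
        if len(ref) == 0:
            raise InputError("no reference genes present in the count matrix")
        counts = counts.loc[ref]
    arr = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        loggeo = np.mean(np.log(arr), axis=1)
    ok = np.isfinite(loggeo)
    if not ok.any():
        raise InputError("no gene has positive counts in every sample")
    ratios = np.log(arr[ok]) - loggeo[ok, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.columns)


def autosomal_reference_genes(matrix: ExpressionMatrix) -> Optional[pd.Index]:
    """Genes outside the Z-linked classes, for size-factor estimation."""
    if matrix.region_class is None:
        return None
    classes = matrix.region_class.reindex(matrix.counts.index)
    ref = matrix.counts.index[~classes.isin(cfg.Z_CLASSES)]
    return ref if len(ref) else None


def normalized_expression(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Length- and size-factor-normalized expression (composition-robust).

    Size factors are estimated from non-Z genes when region classes are
    known, so the DR dosage effect cannot bias the per-sample scaling.
    """
    sf = median_of_ratios_size_factors(matrix.counts, autosomal_reference_genes(matrix))
    return matrix.counts.div(sf, axis=1).div(matrix.lengths, axis=0) * 1e3


def mf_log2_ratios(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    min_expr: float = 1.0,
    pseudocount: float = 0.01,
) -> pd.Series:
    """Per-gene log2 of (mean male expression / mean female expression).

    ``expr`` is any normalized expression matrix (TPM or size-factor
    normalized).  Genes below ``min_expr`` in both sexes are dropped; the
    pseudocount keeps ratios finite for genes silent in one sex.
    """
    male = [s for s in expr.columns if samples.loc[s, "sex"] == "M"]
    female = [s for s in expr.columns if samples.loc[s, "sex"] == "F"]
    if not male or not female:
        raise InputError("need at least one sample of each sex")
    m = expr[male].mean(axis=1)
    f = expr[female].mean(axis=1)
    keep = (m >= min_expr) | (f >= min_expr)
    return np.log2((m[keep] + pseudocount) / (f[keep] + pseudocount))


def dosage_summary(ratios: pd.Series, region_class: pd.Series) -> dict:
    """Per-class medians/means of log2 M/F ratios and the compensation call.

    Returns {class: {median_log2, mean_log2, median_ratio, mean_ratio, n}}
    plus ``partial_compensation_dr``: True when the DR median log2 ratio lies
    strictly between 0 (full compensation) and 1 (no compensation).
    """
    classes = region_class.reindex(ratios.index)
    out: Dict[str, dict] = {}
    for klass, vals in ratios.groupby(classes):
        if len(vals) == 0:
            continue
        med = float(np.median(vals))
        mean = float(np.mean(vals))
        out[str(klass)] = {
            "median_log2": med,
            "mean_log2": mean,
            "median_ratio": float(2.0**med),
            "mean_ratio": float(2.0**mean),
            "n": int(len(vals)),
        }
    for klass in (cfg.PAR, cfg.DR):
        if klass not in out:
            log.warning("region class %s absent from dosage summary", klass)
    dr_med = out.get(cfg.DR, {}).get("median_log2")
    flag = dr_med is not None and 0.0 < dr_med < 1.0
    return {"classes": out, "partial_compensation_dr": bool(flag)}


# ---------------------------------------------------------------------------
# sex-biased gene calling


def _moderated_t(
    ym: np.ndarray, yf: np.ndarray
) -> tuple:
    """Empirical-Bayes moderated t on log2 expression (limma-trend style).

    Per-gene pooled variances are shrunk toward a running-mean variance
    trend over average log-expression; the prior degrees of freedom are
    estimated by the method of moments on log sample variances (scaled
    inverse-chi-square prior).  Returns (lfc, p, prior_df).
    """
    from scipy import optimize, special

    nm, nf = ym.shape[1], yf.shape[1]
    lfc = ym.mean(axis=1) - yf.mean(axis=1)
    df = nm + nf - 2
    s2 = np.maximum(
        (ym.var(axis=1, ddof=1) * (nm - 1) + yf.var(axis=1, ddof=1) * (nf - 1)) / df,
        1e-10,
    )
    e = np.log(s2) - special.digamma(df / 2) + np.log(df / 2)
    amean = (ym.mean(axis=1) + yf.mean(axis=1)) / 2
    order = np.argsort(amean, kind="stable")
    k = max(len(e) // 20, min(25, len(e)))
    kernel = np.ones(k) / k
    sorted_e = e[order]
    pad = np.concatenate(
        [
            np.full(k // 2, sorted_e[:k].mean()),
            sorted_e,
            np.full(k - k // 2 - 1, sorted_e[-k:].mean()),
        ]
    )
    etrend = np.empty_like(e)
    etrend[order] = np.convolve(pad, kernel, mode="valid")
    evar = (e - etrend).var(ddof=1) - special.polygamma(1, df / 2)
    if evar > 0:
        d0 = float(
            optimize.brentq(lambda d: special.polygamma(1, d / 2) - evar, 0.01, 1e7)
        )
        s02 = np.exp(etrend + special.digamma(d0 / 2) - np.log(d0 / 2))
    else:
        d0 = 1e7
        s02 = np.exp(etrend)
    s2_post = (d0 * s02 + df * s2) / (d0 + df)
    tstat = lfc / np.sqrt(s2_post * (1.0 / nm + 1.0 / nf))
    p = 2.0 * stats.t.sf(np.abs(tstat), min(df + d0, 1e6))
    return lfc, p, d0


def call_sex_biased(
    matrix: ExpressionMatrix,
    fdr: float = 0.05,
    pseudocount: float = 0.5,
    min_mean_count: float = 10.0,
) -> pd.DataFrame:
    """Differential expression between sexes on normalized counts.

    A simplified stand-in for a full DE package: counts are normalized with
    median-of-ratios size factors (autosome-referenced when region classes
    are known), log2-transformed with a pseudocount, and tested with an
    empirical-Bayes moderated t-statistic whose gene variances are shrunk
    toward a mean-expression variance trend.  Genes below ``min_mean_count``
    normalized counts in both sexes are not tested (reported unbiased with
    q = 1), the standard independent filter that removes the skew-dominated
    low-count stratum.  Benjamini-Hochberg controls the FDR at ``fdr``.
    Externally produced calls (TSV with gene_id, lfc, qvalue) can be used
    instead via :func:`sex_bias_calls_from_table`.

    Returns a DataFrame indexed by gene with columns lfc, p_value, q_value,
    call, region_class.
    """
    male = matrix.sex_columns("M")
    female = matrix.sex_columns("F")
    if len(male) < 2 or len(female) < 2:
        raise InputError(
            "need >= 2 replicates per sex to estimate dispersion; supply external "
            "calls via sex_bias_calls_from_table instead"
        )
    sf = median_of_ratios_size_factors(matrix.counts, autosomal_reference_genes(matrix))
    norm = matrix.counts.div(sf, axis=1)
    xm = norm[male].to_numpy(dtype=float)
    xf = norm[female].to_numpy(dtype=float)
    keep = (xm.mean(axis=1) >= min_mean_count) | (xf.mean(axis=1) >= min_mean_count)

    lfc = np.zeros(len(norm))
    p = np.ones(len(norm))
    q = np.ones(len(norm))
    if keep.sum() >= 10:
        lfc_k, p_k, _ = _moderated_t(
            np.log2(xm[keep] + pseudocount), np.log2(xf[keep] + pseudocount)
        )
        _, q_k, _, _ = multipletests(p_k, method="fdr_bh")
        lfc[keep], p[keep], q[keep] = lfc_k, p_k, q_k

    call = np.where(
        (q < fdr) & (lfc > 0), "male-biased", np.where((q < fdr) & (lfc < 0), "female-biased", "unbiased")
    )
    region = (
        matrix.region_class.reindex(matrix.counts.index).fillna(cfg.OTHER)
        if matrix.region_class is not None
        else pd.Series(cfg.OTHER, index=matrix.counts.index)
    )
    return pd.DataFrame(
        {
            "lfc": lfc,
            "p_value": p,
            "q_value": q,
            "call": call,
            "region_class": region.to_numpy(),
        },
        index=matrix.counts.index,
    )


def sex_bias_calls_from_table(
    table: pd.DataFrame, region_class: pd.Series, fdr: float = 0.05
) -> pd.DataFrame:
    """Adapt externally produced DE results (gene_id, lfc, qvalue) to calls."""
    required = {"gene_id", "lfc", "qvalue"}
    if not required <= set(table.columns):
        raise InputError(f"external calls need columns {sorted(required)}")
    df = table.set_index("gene_id")
    call = np.where(
        (df["qvalue"] < fdr) & (df["lfc"] > 0),
        "male-biased",
        np.where((df["qvalue"] < fdr) & (df["lfc"] < 0), "female-biased", "unbiased"),
    )
    return pd.DataFrame(
        {
            "lfc": df["lfc"],
            "p_value": np.nan,
            "q_value": df["qvalue"],
            "call": call,
            "region_class": region_class.reindex(df.index).fillna(cfg.OTHER).to_numpy(),
        },
        index=df.index,
    )


def par_enrichment_test(
    calls: pd.DataFrame,
    region: str,
    bias: str = "male",
    autosome_classes: tuple = (cfg.CHR4, cfg.CHR5, cfg.AUTOSOME_MACRO),
) -> dict:
    """Fisher's exact test for enrichment of sex-biased genes in a region.

    Builds the 2x2 table (biased, unbiased) x (region, autosomes) and
    returns the table, sample odds ratio (NaN when a margin is empty, with
    p = 1), and the two-sided p-value.  ``region`` is PAR, DR, or Z
    (= PAR + DR).
    """
    if bias not in ("male", "female"):
        raise InputError("bias must be 'male' or 'female'")
    label = f"{bias}-biased"
    classes = calls["region_class"]
    if region == "Z":
        in_region = classes.isin(cfg.Z_CLASSES)
    else:
        in_region = classes == region
    in_auto = classes.isin(autosome_classes)
    biased = calls["call"] == label

    a = int((in_region & biased).sum())
    b = int((in_region & ~biased).sum())
    c = int((in_auto & biased).sum())
    d = int((in_auto & ~biased).sum())
    table = [[a, b], [c, d]]
    if min(a + b, c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        return {
            "table": table,
            "odds_ratio": float("nan"),
            "p_value": 1.0,
            "region": region,
            "bias": bias,
            "flag": "degenerate-margin",
        }
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return {
        "table": table,
        "odds_ratio": float(odds),
        "p_value": p,
        "region": region,
        "bias": bias,
        "flag": None,
    }
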