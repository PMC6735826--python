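"""Chromosome-wide dN/dS with bootstrap and permutation resampling.

The estimator is a ratio of sums: dS is total synonymous substitutions over
total synonymous sites across all genes of a region, dN likewise for
nonsynonymous ones, and omega = dN/dS.  This is a length-weighted average of
per-gene rates and is far more stable than averaging per-gene ratios, whose
denominators can be tiny.  Confidence intervals come from resampling genes
with replacement (percentile by default, BCa optionally); region-versus-
autosome contrasts use a two-sided label-permutation test with an add-one
p-value estimator, so p is never zero and never below 1/(n_perm + 1).

Gene tables are plain pandas DataFrames with the columns of
``DIVERGENCE_COLUMNS``; per-gene dn/ds columns are derived conveniences, the
estimators only consume substitution and site counts.
"""

from __future__ import annotations

import itertools
import logging
import math
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from . import config as cfg

log = logging.getLogger(__name__)

DIVERGENCE_COLUMNS = (
    "gene_id",
    "chromosome",
    "region_class",
    "n_sites",
    "s_sites",
    "n_subs",
    "s_subs",
    "dn",
    "ds",
)

_COUNT_COLS = ["n_subs", "s_subs", "n_sites", "s_sites"]


@dataclass
class ChromosomeRates:
    """Aggregated rates for one region class."""

    region_class: str
    dn: float
    ds: float
    omega: float  # NaN when undefined (aggregate dS == 0)
    n_genes: int
    ci_dn: Optional[tuple] = None
    ci_ds: Optional[tuple] = None
    ci_omega: Optional[tuple] = None
    seed: Optional[int] = None

    @property
    def omega_defined(self) -> bool:
        return math.isfinite(self.omega)

    def to_dict(self) -> dict:
        def ci(x):
            return None if x is None else [float(x[0]), float(x[1])]

        return {
            "region_class": self.region_class,
            "dn": float(self.dn),
            "ds": float(self.ds),
            "omega": float(self.omega) if self.omega_defined else None,
            "n_genes": int(self.n_genes),
            "ci_dn": ci(self.ci_dn),
            "ci_ds": ci(self.ci_ds),
            "ci_omega": ci(self.ci_omega),
            "seed": self.seed,
        }


@dataclass
class ComparisonResult:
    """A region-vs-reference contrast with its resampling p-value."""

    region_class: str
    reference_class: str
    statistic_name: str
    observed_difference: float
    p_value: float
    n_permutations: int
    direction: str  # faster | slower | ns
    n_region: int = 0
    n_reference: int = 0
    seed: Optional[int] = None
    medians: Optional[tuple] = None

    def to_dict(self) -> dict:
        return {
            "region_class": self.region_class,
            "reference_class": self.reference_class,
            "statistic_name": self.statistic_name,
            "observed_difference": float(self.observed_difference),
            "p_value": float(self.p_value),
            "n_permutations": int(self.n_permutations),
            "direction": self.direction,
            "n_region": int(self.n_region),
            "n_reference": int(self.n_reference),
            "seed": self.seed,
            "medians": None if self.medians is None else [float(m) for m in self.medians],
        }


def validate_divergence_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(_COUNT_COLS) - set(df.columns)
    if missing:
        raise InputError(f"divergence table missing columns: {sorted(missing)}")
    if (df[["n_sites", "s_sites"]] <= 0).any().any():
        raise InputError("site counts must be positive")
    if (df[["n_subs", "s_subs"]] < 0).any().any():
        raise InputError("substitution counts must be non-negative")
    return df


# ---------------------------------------------------------------------------


def filter_divergence_outliers(
    records: pd.DataFrame, max_total_subs: float = 1500.0
) -> pd.DataFrame:
    """Drop genes whose total substitution count strictly exceeds the cap.

    Saturated genes (alignment or annotation artifacts) otherwise dominate
    the chromosome-wide sums.  The total is nonsynonymous + synonymous; a
    gene at exactly the cap is retained.
    """
    validate_divergence_table(records)
    total = records["n_subs"] + records["s_subs"]
    keep = total <= max_total_subs
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("outlier filter removed %d genes (> %g substitutions)", n_removed, max_total_subs)
    return records[keep].reset_index(drop=True)


def aggregate_rates(records: pd.DataFrame, region_class: str = "") -> ChromosomeRates:
    """Ratio-of-sums dN, dS and omega over a set of genes."""
    if len(records) == 0:
        raise InputError("cannot aggregate an empty gene set")
    validate_divergence_table(records)
    n_subs = float(records["n_subs"].sum())
    s_subs = float(records["s_subs"].sum())
    n_sites = float(records["n_sites"].sum())
    s_sites = float(records["s_sites"].sum())
    dn = n_subs / n_sites
    ds = s_subs / s_sites
    omega = dn / ds if ds > 0 else float("nan")
    if not region_class and "region_class" in records.columns:
        classes = records["region_class"].unique()
        region_class = classes[0] if len(classes) == 1 else "MIXED"
    return ChromosomeRates(
        region_class=region_class, dn=dn, ds=ds, omega=omega, n_genes=len(records)
    )


def _stat_from_sums(sums: np.ndarray, statistic: str) -> np.ndarray:
    """Vectorized statistic from stacked [n_subs, s_subs, n_sites, s_sites] sums."""
    with np.errstate(divide="ignore", invalid="ignore"):
        dn = sums[..., 0] / sums[..., 2]
        ds = sums[..., 1] / sums[..., 3]
        if statistic == "dn":
            return dn
        if statistic == "ds":
            return ds
        if statistic == "omega":
            return np.where(ds > 0, dn / np.where(ds > 0, ds, 1.0), np.nan)
    raise InputError(f"unknown statistic {statistic!r}")


def bootstrap_ci(
    records: pd.DataFrame,
    statistic: str = "omega",
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    method: str = "percentile",
) -> tuple:
    """Gene-resampling confidence interval for an aggregated rate.

    Genes are resampled with replacement ``n_boot`` times and the
    ratio-of-sums statistic recomputed per replicate.  ``method`` is
    "percentile" (default) or "bca" (bias-corrected and accelerated, with a
    jackknife acceleration estimate).  Replicates where the statistic is
    undefined (zero synonymous substitutions resampled) are discarded; more
    than 50% undefined raises.
    """
    validate_divergence_table(records)
    values = records[_COUNT_COLS].to_numpy(dtype=float)
    n = values.shape[0]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    sums = values[idx].sum(axis=1)
    reps = _stat_from_sums(sums, statistic)
    finite = np.isfinite(reps)
    if finite.sum() < 0.5 * n_boot:
        raise InputError(
            f"{statistic} undefined in {n_boot - int(finite.sum())}/{n_boot} bootstrap "
            "replicates; the gene set has too few synonymous substitutions"
        )
    reps = reps[finite]
    alpha = (1.0 - level) / 2.0
    if method == "percentile":
        lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
        return float(lo), float(hi)
    if method != "bca":
        raise InputError(f"unknown bootstrap method {method!r}")
    theta = float(_stat_from_sums(values.sum(axis=0), statistic))
    z0 = stats.norm.ppf(np.clip(np.mean(reps < theta), 1e-9, 1 - 1e-9))
    total = values.sum(axis=0)
    jack = _stat_from_sums(total[None, :] - values, statistic)
    jack = jack[np.isfinite(jack)]
    jm = jack.mean()
    num = np.sum((jm - jack) ** 3)
    den = 6.0 * np.sum((jm - jack) ** 2) ** 1.5
    a = num / den if den > 0 else 0.0
    zl, zh = stats.norm.ppf([alpha, 1.0 - alpha])
    qlo = stats.norm.cdf(z0 + (z0 + zl) / (1 - a * (z0 + zl)))
    qhi = stats.norm.cdf(z0 + (z0 + zh) / (1 - a * (z0 + zh)))
    lo, hi = np.quantile(reps, [qlo, qhi])
    return float(lo), float(hi)


def permutation_test(
    records_region: pd.DataFrame,
    records_reference: pd.DataFrame,
    statistic: str = "omega",
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    exhaustive: bool = False,
    region_class: str = "",
    reference_class: str = "",
) -> ComparisonResult:
    """Two-sided label-permutation test of an aggregated-rate difference.

    The observed statistic is stat(region) - stat(reference); gene labels
    are permuted over the pooled set preserving group sizes.  The reported
    p-value uses the add-one estimator (1 + #{|T_perm| >= |T_obs|}) /
    (n_perm + 1).  With ``exhaustive`` every distinct split is enumerated
    (only feasible for small groups) and the plain proportion is returned,
    the observed split being part of the enumeration.
    """
    if len(records_region) == 0 or len(records_reference) == 0:
        raise InputError("both groups must be non-empty")
    validate_divergence_table(records_region)
    validate_divergence_table(records_reference)
    v1 = records_region[_COUNT_COLS].to_numpy(dtype=float)
    v2 = records_reference[_COUNT_COLS].to_numpy(dtype=float)
    n1, n2 = v1.shape[0], v2.shape[0]
    pooled = np.vstack([v1, v2])
    total = pooled.sum(axis=0)

    def diff_from_region_sums(region_sums: np.ndarray) -> np.ndarray:
        ref_sums = total[None, :] - region_sums if region_sums.ndim == 2 else total - region_sums
        return _stat_from_sums(region_sums, statistic) - _stat_from_sums(ref_sums, statistic)

    t_obs = float(diff_from_region_sums(v1.sum(axis=0)))

    if exhaustive:
        n = n1 + n2
        if math.comb(n, n1) > 200_000:
            raise InputError("exhaustive enumeration infeasible for these group sizes")
        diffs = []
        for combo in itertools.combinations(range(n), n1):
            s = pooled[list(combo)].sum(axis=0)
            diffs.append(float(diff_from_region_sums(s)))
        diffs = np.asarray(diffs)
        finite = np.isfinite(diffs)
        n_tot = len(diffs)
        count = int(np.sum(np.abs(diffs[finite]) >= abs(t_obs) - 1e-12))
        p = count / n_tot
        n_used = n_tot
    else:
        rng = np.random.default_rng(seed)
        keys = rng.random((n_perm, n1 + n2))
        idx = np.argpartition(keys, n1 - 1, axis=1)[:, :n1]
        region_sums = np.stack(
            [pooled[:, j][idx].sum(axis=1) for j in range(4)], axis=-1
        )
        diffs = diff_from_region_sums(region_sums)
        exceed = np.abs(diffs) >= abs(t_obs) - 1e-12
        count = int(np.nansum(np.where(np.isfinite(diffs), exceed, False)))
        p = (1.0 + count) / (n_perm + 1.0)
        n_used = n_perm

    if not math.isfinite(t_obs) or p >= alpha:
        direction = "ns"
    else:
        direction = "faster" if t_obs > 0 else "slower"
    return ComparisonResult(
        region_class=region_class or _class_of(records_region),
        reference_class=reference_class or _class_of(records_reference),
        statistic_name=statistic,
        observed_difference=t_obs,
        p_value=float(p),
        n_permutations=n_used,
        direction=direction,
        n_region=n1,
        n_reference=n2,
        seed=None if exhaustive else seed,
    )


def _class_of(df: pd.DataFrame) -> str:
    if "region_class" in df.columns:
        u = df["region_class"].unique()
        if len(u) == 1:
            return str(u[0])
        return "+".join(sorted(map(str, u)))
    return ""


# ---------------------------------------------------------------------------


def faster_z_report(
    records: pd.DataFrame,
    reference_classes: Sequence[str] = cfg.REFERENCE_CLASSES,
    statistics: Sequence[str] = ("dn", "ds", "omega"),
    n_boot: int = 1000,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    max_total_subs: float = 1500.0,
    boundary_bp: Optional[int] = None,
    boundary_exclusion_bp: int = 0,
) -> dict:
    """Faster-Z / faster-PAR / faster-DR table for one species.

    Aggregates rates with bootstrap CIs for Z (= PAR + DR), PAR, DR and the
    pooled autosomal reference, then permutation-tests each Z group against
    the reference for every statistic.  With ``boundary_bp`` and a positive
    ``boundary_exclusion_bp`` the analysis is repeated after dropping Z-linked
    genes whose start lies within the exclusion distance of the PAR/DR
    boundary, a robustness check against boundary misannotation (requires a
    ``start`` column).

    Returns {"rates": {class: ChromosomeRates}, "comparisons": [ComparisonResult],
    "n_outliers_removed": int, and optionally "boundary_robustness": {...}}.
    """
    validate_divergence_table(records)
    n_before = len(records)
    records = filter_divergence_outliers(records, max_total_subs)
    n_removed = n_before - len(records)

    ref = records[records["region_class"].isin(reference_classes)]
    if len(ref) == 0:
        raise InputError(f"no genes in reference classes {tuple(reference_classes)}")
    ref_name = "+".join(reference_classes)

    groups = {}
    z_mask = records["region_class"].isin(cfg.Z_CLASSES)
    if z_mask.any():
        groups["Z"] = records[z_mask]
    for klass in cfg.Z_CLASSES:
        sub = records[records["region_class"] == klass]
        if len(sub):
            groups[klass] = sub
        else:
            log.warning("region class %s has no genes; row omitted", klass)

    ss = np.random.SeedSequence(seed)
    seeds = iter(ss.generate_state(4 * (len(groups) + 1) * len(statistics)).tolist())

    rates = {}
    comparisons = []
    ref_rates = _rates_with_ci(ref, ref_name, statistics, n_boot, next(seeds))
    rates[ref_name] = ref_rates
    for name, sub in groups.items():
        rates[name] = _rates_with_ci(sub, name, statistics, n_boot, next(seeds))
        for statistic in statistics:
            comparisons.append(
                permutation_test(
                    sub,
                    ref,
                    statistic=statistic,
                    n_perm=n_perm,
                    seed=next(seeds) % (2**31),
                    alpha=alpha,
                    region_class=name,
                    reference_class=ref_name,
                )
            )

    out = {"rates": rates, "comparisons": comparisons, "n_outliers_removed": n_removed}

    if boundary_bp is not None and boundary_exclusion_bp > 0:
        if "start" not in records.columns:
            raise InputError("boundary robustness mode requires a 'start' column")
        near = (
            records["region_class"].isin(cfg.Z_CLASSES)
            & (records["start"] - boundary_bp).abs().le(boundary_exclusion_bp)
        )
        trimmed = records[~near]
        sub_report = faster_z_report(
            trimmed,
            reference_classes=reference_classes,
            statistics=statistics,
            n_boot=n_boot,
            n_perm=n_perm,
            seed=seed + 1,
            alpha=alpha,
            max_total_subs=max_total_subs,
        )
        sub_report["n_genes_excluded"] = int(near.sum())
        out["boundary_robustness"] = sub_report
    return out


def _rates_with_ci(sub, name, statistics, n_boot, seed) -> ChromosomeRates:
    r = aggregate_rates(sub, region_class=name)
    r.seed = int(seed % (2**31))
    cis = {}
    for statistic in statistics:
        try:
            cis[statistic] = bootstrap_ci(sub, statistic, n_boot=n_boot, seed=r.seed)
        except InputError:
            cis[statistic] = None
    r.ci_dn = cis.get("dn")
    r.ci_ds = cis.get("ds")
    r.ci_omega = cis.get("omega")
    return r


# ---------------------------------------------------------------------------
# PAML free-ratio branch table reader

_BRANCH_HEADER = re.compile(r"^\s*branch\s+t\s+N\s+S\s+dN/dS\s+dN\s+dS\s+N\*dN\s+S\*dS")
_BRANCH_ROW = re.compile(
    r"^\s*(\d+\.\.\d+)\s+" + r"\s+".join([r"([-\d.eE+]+)"] * 8) + r"\s*$"
)


def read_paml_branch_table(path: str) -> pd.DataFrame:
    """Parse the per-branch rate table of a codeml free-ratio output file.

    Returns one row per branch with columns branch, t, N, S, dn_ds, dn, ds,
    n_subs (N*dN), s_subs (S*dS).  Use :func:`paml_branches_to_records` to
    turn a chosen branch per gene into a divergence table row.
    """
    rows = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            if _BRANCH_HEADER.match(line):
                in_table = True
                continue
            if in_table:
                m = _BRANCH_ROW.match(line)
                if m:
                    branch = m.group(1)
                    t, n, s, dnds, dn, ds, ndn, sds = map(float, m.groups()[1:])
                    rows.append(
                        {
                            "branch": branch,
                            "t": t,
                            "N": n,
                            "S": s,
                            "dn_ds": dnds,
                            "dn": dn,
                            "ds": ds,
                            "n_subs": ndn,
                            "s_subs": sds,
                        }
                    )
                elif rows and line.strip() == "":
                    break
    if not rows:
        raise InputError(f"no free-ratio branch table found in {path}")
    return pd.DataFrame(rows)


def paml_branches_to_records(
    tables: dict,
    branch_by_gene: dict,
    chromosome_by_gene: dict,
    region_class_by_gene: dict,
) -> pd.DataFrame:
    """Assemble GeneDivergenceRecord rows from parsed per-gene branch tables.

    ``tables`` maps gene_id -> DataFrame from :func:`read_paml_branch_table`;
    ``branch_by_gene`` picks the focal (terminal) branch label per gene.
    """
    rows = []
    for gene_id, table in tables.items():
        branch = branch_by_gene[gene_id]
        hit = table[table["branch"] == branch]
        if len(hit) != 1:
            raise InputError(f"branch {branch} not found for gene {gene_id}")
        r = hit.iloc[0]
        rows.append(
            {
                "gene_id": gene_id,
                "chromosome": chromosome_by_gene.get(gene_id, ""),
                "region_class": region_class_by_gene.get(gene_id, cfg.OTHER),
                "n_sites": float(r["N"]),
                "s_sites": float(r["S"]),
                "n_subs": float(r["n_subs"]),
                "s_subs": float(r["s_subs"]),
                "dn": float(r["dn"]),
                "ds": float(r["ds"]),
            }
        )
    return pd.DataFrame(rows, columns=list(DIVERGENCE_COLUMNS))
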