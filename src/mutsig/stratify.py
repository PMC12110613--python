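"""Cohort stratification and comparison.

Prevalence/dominance summaries per signature group, enrichment tests of
dominant-signature composition across strata (exact Fisher for 2x2, seeded
Monte-Carlo exact test with fixed margins for larger tables), rank-based
distribution comparisons (Mann-Whitney U, Kolmogorov-Smirnov,
Kruskal-Wallis), Gaussian kernel densities of contribution values, and the
split of TNBC samples into HRd / non-HRd / unassigned classes:
bi-allelic BRCA1/2/PALB2 inactivation defines HRd; otherwise an HRD
genomic-scar score below 0.1 defines non-HRd; everything else is
unassigned. Distribution comparisons consider only samples where the
signature is detected (nonzero contribution).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

logger = logging.getLogger(__name__)

GRADES = ("G1", "G2", "G3", "unknown")

ANNOTATION_COLUMNS = ["sample_id", "grade", "subtype", "hrd_score", "biallelic_hrd_gene"]


class DegenerateBandwidthError(ValueError):
    """Kernel density bandwidth undefined for a constant sample."""


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Load a cohort annotation TSV (grade, subtype, HRD score, bi-allelic
    BRCA1/2/PALB2 flag), validating score range and grade labels."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    df["grade"] = df["grade"].fillna("unknown")
    bad = set(df["grade"]) - set(GRADES)
    if bad:
        raise ValueError(f"unknown grade labels: {sorted(bad)}")
    scores = df["hrd_score"].dropna()
    if ((scores < 0) | (scores > 1)).any():
        raise ValueError("hrd_score must lie in [0, 1]")
    df["biallelic_hrd_gene"] = df["biallelic_hrd_gene"].astype(bool)
    return df.set_index("sample_id")


@dataclass
class StratifiedSummary:
    """Container for per-stratum summaries and between-stratum tests."""

    per_stratum: dict[str, pd.DataFrame] = field(default_factory=dict)
    enrichment: dict[str, float] = field(default_factory=dict)
    distribution_tests: pd.DataFrame | None = None


def summarize_prevalence(
    presence: pd.DataFrame,
    contributions: pd.DataFrame,
    dominants: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-group cohort summary.

    Prevalence is 100 * present / N (reported to 2 decimal places, like the
    percentages in cohort reports); contribution statistics are taken over
    the samples where the group is present.
    """
    N = presence.shape[0]
    rows = []
    for g in presence.columns:
        mask = presence[g].astype(bool)
        n_present = int(mask.sum())
        vals = contributions.loc[mask.values, g] if n_present else pd.Series(dtype=float)
        row = {
            "group": g,
            "n_present": n_present,
            "n_total": N,
            "prevalence_pct": round(100.0 * n_present / N, 2) if N else np.nan,
            "mean_contribution": round(float(vals.mean()), 4) if n_present else np.nan,
            "min_contribution": round(float(vals.min()), 4) if n_present else np.nan,
            "max_contribution": round(float(vals.max()), 4) if n_present else np.nan,
        }
        if dominants is not None:
            n1 = int((dominants["first_dominant"] == g).sum())
            n2 = int((dominants["second_dominant"] == g).sum())
            row["first_dominant_n"] = n1
            row["first_dominant_pct"] = round(100.0 * n1 / N, 2)
            row["second_dominant_n"] = n2
            row["second_dominant_pct"] = round(100.0 * n2 / N, 2)
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def _log_table_prob(table: np.ndarray) -> float:
    """Log probability of an R x C table under the fixed-margins
    (multiple hypergeometric) null."""
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(r + 1).sum()
        + gammaln(c + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def enrichment_test(table, seed: int = 0, n_draws: int = 100_000) -> float:
    """Exact test of independence on a contingency table.

    2x2 tables use the two-sided Fisher exact test (sum of table
    probabilities <= the observed one). Larger tables use a seeded
    Monte-Carlo exact test with fixed margins: ``n_draws`` tables are
    sampled, and the p-value is the add-one-smoothed fraction whose
    probability under the null does not exceed the observed table's.
    Zero-margin rows/columns are dropped with a warning.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(table < 0):
        raise ValueError("contingency table entries must be non-negative")
    keep_r = table.sum(axis=1) > 0
    keep_c = table.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping zero-margin rows/columns from contingency table")
        table = table[keep_r][:, keep_c]
        if table.ndim != 2 or min(table.shape) < 2:
            raise ValueError("table degenerate after dropping zero margins")
    if table.shape == (2, 2):
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    row_m, col_m = table.sum(axis=1), table.sum(axis=0)
    obs = _log_table_prob(table)
    rng = np.random.default_rng(seed)
    sampler = stats.random_table(row_m, col_m)
    draws = np.asarray(sampler.rvs(n_draws, random_state=rng))
    # per-draw log probability; the margin/total terms are constant
    const = gammaln(row_m + 1).sum() + gammaln(col_m + 1).sum() - gammaln(table.sum() + 1)
    logp = const - gammaln(draws + 1).sum(axis=(1, 2))
    exceed = int(np.sum(logp <= obs + 1e-9))
    return float((exceed + 1) / (n_draws + 1))


@dataclass
class DistComparison:
    mwu_stat: float
    mwu_p: float
    ks_stat: float
    ks_p: float
    n_a: int
    n_b: int
    flag: str = ""


def compare_distributions(values_a, values_b, detected_only: bool = True) -> DistComparison:
    """Two-sided Mann-Whitney U and Kolmogorov-Smirnov comparison.

    With ``detected_only`` (the default for contribution values) only
    strictly positive values enter the comparison, matching density plots
    that show samples with nonzero counts only.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if detected_only:
        a, b = a[a > 0], b[b > 0]
    if a.size < 2 or b.size < 2:
        return DistComparison(np.nan, np.nan, np.nan, np.nan, a.size, b.size, "insufficient-data")
    mwu = stats.mannwhitneyu(a, b, alternative="two-sided")
    ks = stats.ks_2samp(a, b, alternative="two-sided")
    return DistComparison(
        float(mwu.statistic), float(mwu.pvalue), float(ks.statistic), float(ks.pvalue),
        a.size, b.size,
    )


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis rank-sum H with tie correction and chi-square p."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        # degenerate: every observation identical
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def kernel_density(
    values, bandwidth: str | float = "silverman", grid_size: int = 256
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density on a regular grid spanning the data +- 3
    bandwidths. Returns ``(grid, density)``; the trapezoidal integral of the
    curve is ~1."""
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < 2:
        raise DegenerateBandwidthError("kernel density undefined for a constant sample")
    kde = stats.gaussian_kde(x, bw_method=bandwidth)
    h = float(kde.factor * x.std(ddof=1))
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_size)
    return grid, kde(grid)


def split_hrd_status(annotations: pd.DataFrame) -> pd.Series:
    """Partition samples into HRd / non-HRd / unassigned.

    Bi-allelic BRCA1/2/PALB2 inactivation -> HRd; otherwise HRD score < 0.1
    -> non-HRd; a score >= 0.1 (or missing without the flag) -> unassigned.
    """
    flags = annotations["biallelic_hrd_gene"].astype(bool)
    score = annotations["hrd_score"]
    status = pd.Series("unassigned", index=annotations.index, name="hrd_status")
    status[flags] = "HRd"
    status[(~flags) & score.notna() & (score < 0.1)] = "non-HRd"
    return status


def stratified_compare(
    profiles: pd.DataFrame,
    annotations: pd.DataFrame,
    stratifier: str = "grade",
    seed: int = 0,
) -> StratifiedSummary:
    """Per-stratum prevalence summaries plus between-stratum tests.

    ``stratifier`` is "grade", "hrd_status" (derived via
    :func:`split_hrd_status`, dropping unassigned samples) or any annotation
    column. Enrichment is tested on the dominant-signature x stratum
    contingency tables; contribution distributions of every group are
    compared between each stratum pair.
    """
    ann = annotations.reindex(profiles.index)
    if stratifier == "hrd_status":
        strata = split_hrd_status(ann)
        strata = strata[strata != "unassigned"]
    elif stratifier in ann.columns:
        strata = ann[stratifier].dropna().astype(str)
    else:
        raise ValueError(f"unknown stratifier {stratifier!r}")
    profiles = profiles.loc[profiles.index.intersection(strata.index)]
    strata = strata.loc[profiles.index]

    groups = [c[len("contrib_") :] for c in profiles.columns if c.startswith("contrib_")]
    summary = StratifiedSummary()
    for label in sorted(strata.unique()):
        sub = profiles[strata == label]
        if sub.empty:
            logger.warning("stratum %s has no samples; omitted", label)
            continue
        presence = sub[[f"present_{g}" for g in groups]].rename(
            columns=lambda c: c[len("present_") :]
        )
        contrib = sub[[f"contrib_{g}" for g in groups]].rename(
            columns=lambda c: c[len("contrib_") :]
        )
        dominants = sub[["first_dominant", "second_dominant"]]
        summary.per_stratum[label] = summarize_prevalence(presence, contrib, dominants)

    for what in ("first_dominant", "second_dominant", "signature_group"):
        table = pd.crosstab(profiles[what], strata)
        table = table.loc[(table.sum(axis=1) > 0), (table.sum(axis=0) > 0)]
        if table.shape[0] >= 2 and table.shape[1] >= 2:
            summary.enrichment[what] = enrichment_test(table.to_numpy(), seed=seed)

    rows = []
    labels = sorted(strata.unique())
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            for g in groups:
                va = profiles.loc[strata == la, f"contrib_{g}"]
                vb = profiles.loc[strata == lb, f"contrib_{g}"]
                if va.empty or vb.empty:
                    continue
                cmp = compare_distributions(va, vb)
                rows.append(
                    {
                        "stratum_a": la, "stratum_b": lb, "group": g,
                        "mwu_p": cmp.mwu_p, "ks_p": cmp.ks_p,
                        "n_a": cmp.n_a, "n_b": cmp.n_b, "flag": cmp.flag,
                    }
                )
    summary.distribution_tests = pd.DataFrame(rows)
    return summary
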