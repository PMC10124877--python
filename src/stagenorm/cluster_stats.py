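"""Normality-gated group comparisons across clusters.

The cascade: Shapiro-Wilk normality per group and Levene's variance
homogeneity gate the choice of omnibus test.  If every group looks
normal and variances are homogeneous, one-way ANOVA is used with Tukey
HSD post-hoc; otherwise Kruskal-Wallis with Dunn's rank-based post-hoc
(BH-adjusted).  Non-normality with homogeneous variances also routes to
the rank test.  Every decision and p-value is kept in an audit trail so
a re-run on the same data reproduces the identical record.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from stagenorm.ora_enrichment import bh_adjust
from stagenorm.sample_clustering import ClusterAssignment
from stagenorm.stage_normalize import TissueCorrectedMatrix

logger = logging.getLogger(__name__)


@dataclass
class GroupComparison:
    """Full audit trail of one omnibus comparison."""

    grouping: str
    groups: dict[str, np.ndarray]
    shapiro_p: dict[str, float]
    levene_p: float
    branch: str  # "anova" | "kruskal"
    statistic: float
    p_value: float
    posthoc: Optional[pd.DataFrame] = None
    alpha: float = 0.05
    excluded_groups: list[str] = field(default_factory=list)

    @property
    def rejected(self) -> bool:
        return self.p_value <= self.alpha


def _dunn_posthoc(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's z-tests on pooled ranks with a tie correction, BH-adjusted."""
    names = list(groups)
    values = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    sizes = {g: len(groups[g]) for g in names}
    ranks = stats.rankdata(values)
    mean_rank: dict[str, float] = {}
    start = 0
    for g in names:
        mean_rank[g] = float(ranks[start : start + sizes[g]].mean())
        start += sizes[g]
    n = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n - 1))) if n > 1 else 0.0
    rows = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "statistic": z, "p_value": p})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = bh_adjust(df["p_value"].to_numpy())
    return df


def _tukey_posthoc(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    names = list(groups)
    res = stats.tukey_hsd(*[np.asarray(groups[g], dtype=float) for g in names])
    rows = []
    for i, j in itertools.combinations(range(len(names)), 2):
        rows.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "statistic": float(res.statistic[i, j]),
                "p_value": float(res.pvalue[i, j]),
                "p_adjusted": float(res.pvalue[i, j]),  # Tukey is family-wise already
            }
        )
    return pd.DataFrame(rows)


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    grouping: str = "groups",
) -> GroupComparison:
    """Run the gated omnibus comparison on named groups of values.

    Groups with fewer than 3 values are excluded (the normality gate is
    undefined for them); at least 2 usable groups are required.
    Post-hoc tables are attached only when the omnibus test rejects.
    """
    usable: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for g, vals in values_by_group.items():
        arr = np.asarray(list(vals), dtype=float)
        if len(arr) < 3:
            excluded.append(g)
            logger.warning("group %r excluded: only %d values", g, len(arr))
        else:
            usable[g] = arr
    if len(usable) < 2:
        raise ValueError(f"need at least 2 groups with >=3 values, got {len(usable)}")

    shapiro_p: dict[str, float] = {}
    for g, arr in usable.items():
        if np.ptp(arr) == 0:
            shapiro_p[g] = 0.0  # a constant group is maximally non-normal
        else:
            shapiro_p[g] = float(stats.shapiro(arr).pvalue)
    levene_p = float(stats.levene(*usable.values()).pvalue)

    all_normal = all(p >= alpha for p in shapiro_p.values())
    equal_var = levene_p >= alpha
    if all_normal and equal_var:
        branch = "anova"
        stat, p = stats.f_oneway(*usable.values())
    else:
        branch = "kruskal"
        stat, p = stats.kruskal(*usable.values())

    posthoc = None
    if p <= alpha:
        posthoc = _tukey_posthoc(usable) if branch == "anova" else _dunn_posthoc(usable)
    return GroupComparison(
        grouping=grouping,
        groups=usable,
        shapiro_p=shapiro_p,
        levene_p=levene_p,
        branch=branch,
        statistic=float(stat),
        p_value=float(p),
        posthoc=posthoc,
        alpha=alpha,
        excluded_groups=excluded,
    )


def module_means_by_group(
    corrected: TissueCorrectedMatrix,
    module_genes: Sequence[str],
    sample_groups: Mapping[str, Sequence[str]],
) -> dict[str, np.ndarray]:
    """Per-sample mean module expression, grouped.

    Each sample contributes one value: the mean of the module's genes in
    that sample.  This keeps samples (not gene-sample cells) as the
    statistical unit.
    """
    sub = corrected.L.loc[list(module_genes)]
    return {
        g: sub[list(samples)].mean(axis=0).to_numpy()
        for g, samples in sample_groups.items()
        if len(samples) > 0
    }


def compare_modules_across_clusters(
    corrected: TissueCorrectedMatrix,
    clusters: ClusterAssignment,
    module_genes: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
) -> dict[str, GroupComparison]:
    """One omnibus comparison per module, clusters as groups."""
    results = {}
    for module, genes in module_genes.items():
        groups = {
            f"cluster{c}": clusters.samples_in(c)
            for c in sorted(clusters.labels.unique())
        }
        values = module_means_by_group(corrected, genes, groups)
        try:
            results[module] = compare_groups(values, alpha=alpha, grouping=f"module:{module}")
        except ValueError as exc:
            logger.warning("module %s skipped: %s", module, exc)
    return results


def compare_matched_sites(
    corrected: TissueCorrectedMatrix,
    clusters: ClusterAssignment,
    sites: Mapping[str, str],
    module_genes: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
) -> list[GroupComparison]:
    """Compare the same primary site between clusters, per module.

    For every (module, site) where the site occurs in at least two
    clusters, the site's samples in each cluster form the groups.
    Sites present in a single cluster are skipped with a log entry.
    """
    results: list[GroupComparison] = []
    site_series = pd.Series({s: sites[s] for s in clusters.labels.index})
    for module, genes in module_genes.items():
        for site in sorted(site_series.unique()):
            samples_by_cluster = {}
            for c in sorted(clusters.labels.unique()):
                members = [
                    s for s in clusters.samples_in(c) if site_series[s] == site
                ]
                if members:
                    samples_by_cluster[f"cluster{c}"] = members
            if len(samples_by_cluster) < 2:
                logger.info("site %s present in <2 clusters; skipped", site)
                continue
            values = module_means_by_group(corrected, genes, samples_by_cluster)
            try:
                results.append(
                    compare_groups(
                        values, alpha=alpha, grouping=f"module:{module}|site:{site}"
                    )
                )
            except ValueError as exc:
                logger.warning("comparison %s/%s skipped: %s", module, site, exc)
    return results


def comparisons_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Flatten audit trails into one row per comparison for TSV export."""
    rows = []
    for c in comparisons:
        rows.append(
            {
                "grouping": c.grouping,
                "branch": c.branch,
                "statistic": c.statistic,
                "p_value": c.p_value,
                "levene_p": c.levene_p,
                "min_shapiro_p": min(c.shapiro_p.values()),
                "n_groups": len(c.groups),
                "rejected": c.rejected,
                "n_posthoc_rejected": (
                    int((c.posthoc["p_adjusted"] <= c.alpha).sum())
                    if c.posthoc is not None
                    else 0
                ),
            }
        )
    return pd.DataFrame(rows)
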