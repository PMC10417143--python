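"""Paired tumor/normal score comparison and concordant fold-change filtering.

Ordinal immunostaining intensities (0-3) scored separately on tumor and
adjacent normal tissue are compared pairwise (paired t and Wilcoxon
signed-rank) and as groups (two-sample t and rank-sum); both parametric and
rank-based p-values are always reported.  The concordance filter intersects
two log2 fold-change tables — an overexpression contrast and a knockdown
contrast — keeping genes that move strictly up in the first and strictly
down in the second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError


@dataclass(frozen=True)
class PairedSummary:
    """Summary of per-patient tumor minus normal score differences."""

    n_paired: int
    n_missing_tumor: int
    n_missing_normal: int
    mean_diff: float
    sd_diff: float
    t_p: float
    wilcoxon_p: float
    zero_variance: bool


def paired_difference_summary(table: pd.DataFrame) -> PairedSummary:
    """Mean +/- SD of tumor-normal differences with paired t and signed-rank p.

    Rows missing either side are excluded and counted per side.  A
    zero-variance difference vector cannot support either test: it is
    reported with ``p = 1`` when all differences are zero (no evidence of any
    difference) or ``p = 0`` for a perfectly constant nonzero shift, with the
    ``zero_variance`` flag set either way.
    """
    tumor = pd.to_numeric(table["tumor_score"], errors="coerce")
    normal = pd.to_numeric(table["normal_score"], errors="coerce")
    paired = tumor.notna() & normal.notna()
    n_paired = int(paired.sum())
    if n_paired < 2:
        raise ConfigurationError("need at least 2 complete pairs")
    d = (tumor[paired] - normal[paired]).to_numpy(dtype=float)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        p = 1.0 if mean == 0.0 else 0.0
        return PairedSummary(
            n_paired,
            int(tumor.isna().sum()),
            int(normal.isna().sum()),
            mean,
            sd,
            p,
            p,
            zero_variance=True,
        )
    t_p = float(stats.ttest_rel(tumor[paired], normal[paired]).pvalue)
    nonzero = d[d != 0]
    if nonzero.size == 0:
        w_p = 1.0
    else:
        w_p = float(stats.wilcoxon(nonzero).pvalue)
    return PairedSummary(
        n_paired,
        int(tumor.isna().sum()),
        int(normal.isna().sum()),
        mean,
        sd,
        t_p,
        w_p,
        zero_variance=False,
    )


@dataclass(frozen=True)
class GroupSummary:
    """Two-group comparison of score distributions."""

    n_tumor: int
    n_normal: int
    mean_tumor: float
    sd_tumor: float
    mean_normal: float
    sd_normal: float
    t_p: float
    ranksum_p: float


def group_summary(tumor_scores, normal_scores) -> GroupSummary:
    """Group means +/- SD with two-sample t and rank-sum p-values (two-sided)."""
    t = np.asarray(pd.Series(tumor_scores).dropna(), dtype=float)
    n = np.asarray(pd.Series(normal_scores).dropna(), dtype=float)
    if t.size < 2 or n.size < 2:
        raise ConfigurationError("each group needs at least 2 observations")
    if np.ptp(t) == 0 and np.ptp(n) == 0 and t.mean() == n.mean():
        t_p = ranksum_p = 1.0
    else:
        t_p = float(stats.ttest_ind(t, n).pvalue)
        ranksum_p = float(stats.mannwhitneyu(t, n, alternative="two-sided").pvalue)
    return GroupSummary(
        t.size,
        n.size,
        float(t.mean()),
        float(t.std(ddof=1)),
        float(n.mean()),
        float(n.std(ddof=1)),
        t_p,
        ranksum_p,
    )


@dataclass(frozen=True)
class ConcordantResult:
    """Genes moving up in the first contrast and down in the second."""

    genes: tuple[str, ...]
    count: int


def select_concordant_genes(
    up_table: pd.DataFrame,
    down_table: pd.DataFrame,
    threshold: float = 1.0,
    strict: bool = True,
) -> ConcordantResult:
    """Intersect two fold-change tables on concordant regulation.

    Keeps genes present in both tables with log2FC > threshold in
    ``up_table`` AND log2FC < -threshold in ``down_table`` (strict
    inequalities by default; ``strict=False`` uses >= / <=).
    """
    if up_table.empty or down_table.empty:
        raise ConfigurationError("fold-change tables must be nonempty")
    for tbl, name in ((up_table, "up"), (down_table, "down")):
        if tbl["gene"].duplicated().any():
            raise ConfigurationError(f"duplicate gene identifiers in {name} table")
    merged = up_table.merge(down_table, on="gene", suffixes=("_up", "_down"))
    up = merged["log2fc_up"].to_numpy()
    down = merged["log2fc_down"].to_numpy()
    if strict:
        keep = (up > threshold) & (down < -threshold)
    else:
        keep = (up >= threshold) & (down <= -threshold)
    genes = tuple(sorted(merged.loc[keep, "gene"]))
    return ConcordantResult(genes=genes, count=len(genes))
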