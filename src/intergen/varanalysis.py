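"""Between-replicate variance structure and group-mean clustering.

Summarises how often the group-specific error variances differ (folded F
+ Storey FDR), which group tends to be the most variable among the
heteroscedastic contigs, the distribution of the CC - JC variance
difference, and hierarchically clusters contigs and groups on their mean
log-expression profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .contrasts import GroupFitMatrix, folded_f_matrix
from .design import GROUPS
from .qvalue import storey_q


def hetero_summary(
    gfm: GroupFitMatrix,
    fdr_levels: tuple[float, ...] = (0.05, 0.20),
    pi0: float | None = 1.0,
) -> dict:
    """Fraction of contigs with significantly unequal group variances and,
    among those significant at the strictest level, which group has the
    largest variance.

    pi0 defaults to 1 (BH) for this family: the folded F compares the
    extreme variance pair of each contig, so even homoscedastic contigs
    rarely produce p-values near 1 and the smoother pi0 estimate
    collapses; pinning pi0 keeps the correction conservative.
    """
    p = folded_f_matrix(gfm)
    q = storey_q(p, pi0=pi0)
    levels = sorted(fdr_levels)
    fractions = {lvl: float((q <= lvl).mean()) for lvl in levels}
    strict = levels[0]
    sig = q <= strict
    argmax = np.asarray(GROUPS)[np.argmax(gfm.variances, axis=1)]
    if sig.any():
        tab = pd.Series(argmax[sig]).value_counts(normalize=True)
        argmax_dist = {g: float(tab.get(g, 0.0)) for g in GROUPS}
    else:
        argmax_dist = {g: float("nan") for g in GROUPS}
    return {
        "folded_f_p": p,
        "q": q,
        "fraction_significant": fractions,
        "argmax_level": strict,
        "n_significant": int(sig.sum()),
        "argmax_variance_distribution": argmax_dist,
    }


@dataclass
class VarianceDifference:
    a: str
    b: str
    differences: pd.Series  # s2_a - s2_b on the restricted subset
    share_positive: float
    density: tuple[np.ndarray, np.ndarray] | None  # (grid, density)


def variance_difference(
    gfm: GroupFitMatrix,
    a: str = "CC",
    b: str = "JC",
    restrict: np.ndarray | None = None,
    n_grid: int = 256,
) -> VarianceDifference:
    """Per-contig difference in estimated variance between groups ``a``
    and ``b`` (default CC - JC), optionally restricted to a boolean mask
    (typically the heteroscedasticity-significant subset), with the share
    of positive differences and a Gaussian-kernel density (Silverman
    bandwidth)."""
    ia, ib = GROUPS.index(a), GROUPS.index(b)
    mask = np.ones(len(gfm.contig_ids), bool) if restrict is None else np.asarray(restrict, bool)
    d = gfm.variances[mask, ia] - gfm.variances[mask, ib]
    ids = gfm.contig_ids[mask]
    density = None
    if len(d) >= 3 and np.std(d) > 0:
        kde = stats.gaussian_kde(d, bw_method="silverman")
        grid = np.linspace(d.min(), d.max(), n_grid)
        density = (grid, kde(grid))
    return VarianceDifference(
        a=a,
        b=b,
        differences=pd.Series(d, index=ids, name=f"var_{a}_minus_var_{b}"),
        share_positive=float((d > 0).mean()) if len(d) else float("nan"),
        density=density,
    )


@dataclass
class ClusterResult:
    contig_linkage: np.ndarray | None
    group_linkage: np.ndarray
    contig_order: list[str]
    group_order: list[str]


def cluster_groups(
    group_means: pd.DataFrame,
    metric: str = "euclidean",
    method: str = "average",
) -> ClusterResult:
    """Hierarchical clustering of contigs (rows) and groups (columns) of
    a group-mean expression matrix.

    Rows are sorted by identifier before clustering so tied merges
    resolve deterministically; leaf orders come from scipy's dendrogram
    ordering of the resulting linkage.
    """
    gm = group_means.sort_index()
    group_link = linkage(pdist(gm.T.to_numpy(), metric=metric), method=method)
    group_order = [gm.columns[i] for i in leaves_list(group_link)]
    contig_link = None
    contig_order = list(gm.index)
    if len(gm) > 1:
        contig_link = linkage(pdist(gm.to_numpy(), metric=metric), method=method)
        contig_order = [gm.index[i] for i in leaves_list(contig_link)]
    return ClusterResult(
        contig_linkage=contig_link,
        group_linkage=group_link,
        contig_order=contig_order,
        group_order=list(group_order),
    )
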