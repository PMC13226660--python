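"""Single-cell gene-set activity scoring and per-cluster summaries.

Per-cell activity of a gene set (e.g. the 11-gene COPII signature
Sar1a/Sar1b/Sec23a/Sec23b/Sec24a-d/Sec13/Sec31a/Sec16a) is measured as a
recovery-curve AUC: genes are ranked by count within each cell, and the
area under the cumulative set-member recovery curve over the top fraction
of the ranking is normalized by its maximum attainable value. Per-cluster
summaries give the percentage of expressing cells and a [0,1]-normalized
mean per gene, with clusters under a minimum cell count excluded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_TOP_FRACTION = 0.05
DEFAULT_MIN_CELLS = 10

#: the COPII machinery signature used in the original application
COPII_GENES = [
    "Sar1a", "Sar1b", "Sec23a", "Sec23b", "Sec24a", "Sec24b",
    "Sec24c", "Sec24d", "Sec13", "Sec31a", "Sec16a",
]


def _dense_counts(dataset: ad.AnnData) -> np.ndarray:
    x = dataset.X
    return np.asarray(x.todense()) if hasattr(x, "todense") else np.asarray(x)


def rank_genes_per_cell(dataset: ad.AnnData) -> np.ndarray:
    """Per-cell gene ordering, most expressed first.

    Returns a cells x genes integer array of gene indices; position 0 holds
    the top-ranked gene. Ties are broken by ascending gene index (stable).
    """
    counts = _dense_counts(dataset)
    if counts.shape[1] < 1:
        raise ValueError("dataset has no genes")
    return np.argsort(-counts, axis=1, kind="stable")


def gene_set_auc(
    order: np.ndarray,
    set_indices: np.ndarray,
    top_fraction: float = DEFAULT_TOP_FRACTION,
) -> np.ndarray:
    """Normalized recovery-curve AUC per cell.

    With ``T = ceil(top_fraction * G)`` and ``hits(x)`` the number of set
    genes among the top ``x`` ranks, the raw area ``sum_{x=1..T} hits(x)``
    is normalized by its maximum ``sum_{x=1..T} min(x, |S|)``; an empty set
    scores 0 for every cell.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError(f"top_fraction must lie in (0, 1], got {top_fraction}")
    order = np.atleast_2d(order)
    n_cells, n_genes = order.shape
    t = math.ceil(top_fraction * n_genes)
    set_indices = np.asarray(set_indices, dtype=int)
    if set_indices.size == 0:
        return np.zeros(n_cells)
    # rank (1-based) of each gene in each cell
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(1, n_genes + 1)[None, :].repeat(
        n_cells, axis=0), axis=1)
    set_ranks = ranks[:, set_indices]
    contrib = np.clip(t - set_ranks + 1, 0, None)
    raw = contrib.sum(axis=1)
    x = np.arange(1, t + 1)
    max_raw = np.minimum(x, set_indices.size).sum()
    return raw / max_raw


@dataclass
class GeneSetScore:
    """Per-cell AUC scores for one gene set plus per-cluster means."""

    gene_set_id: str
    auc: pd.Series
    cluster_mean: pd.Series
    top_fraction: float
    n_genes_used: int


def score_gene_sets(
    dataset: ad.AnnData,
    gene_sets: dict[str, list[str]],
    top_fraction: float = DEFAULT_TOP_FRACTION,
) -> dict[str, GeneSetScore]:
    """Score each gene set across all cells; unknown gene ids are dropped."""
    order = rank_genes_per_cell(dataset)
    index = pd.Index(dataset.var_names)
    clusters = dataset.obs["cluster"]
    out = {}
    for set_id, members in gene_sets.items():
        present = [g for g in members if g in index]
        dropped = len(members) - len(present)
        if dropped:
            logger.warning("gene set %s: %d member(s) absent from dataset",
                           set_id, dropped)
        idx = index.get_indexer(present)
        auc = pd.Series(gene_set_auc(order, idx, top_fraction),
                        index=dataset.obs_names, name=set_id)
        cluster_mean = auc.groupby(clusters, observed=True).mean()
        out[set_id] = GeneSetScore(
            gene_set_id=set_id, auc=auc, cluster_mean=cluster_mean,
            top_fraction=top_fraction, n_genes_used=len(present),
        )
    return out


@dataclass
class ClusterSummary:
    """Per-gene x cluster expression summary over included clusters.

    ``pct_expressing`` is 100 x (cells with count > 0) / cluster size;
    ``normalized_mean`` is the per-gene min-max of mean expression across
    included clusters; ``relative_pct`` is each cluster's share of all
    expressing cells (the dot-plot "relative percentage" variant).
    """

    pct_expressing: pd.DataFrame
    mean_expression: pd.DataFrame
    normalized_mean: pd.DataFrame
    relative_pct: pd.DataFrame
    excluded_clusters: dict[str, int] = field(default_factory=dict)
    min_cells: int = DEFAULT_MIN_CELLS


def cluster_summary(
    dataset: ad.AnnData,
    genes: list[str] | None = None,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> ClusterSummary:
    """Summarize expression per cluster, excluding tiny clusters.

    Clusters with fewer than ``min_cells`` cells are excluded from every
    statistic and reported with their cell counts.
    """
    if genes is None:
        genes = list(dataset.var_names)
    missing = [g for g in genes if g not in dataset.var_names.tolist()]
    if missing:
        raise KeyError(f"gene(s) absent from dataset: {missing[:5]}")
    sizes = dataset.obs["cluster"].value_counts()
    excluded = {str(c): int(n) for c, n in sizes.items() if n < min_cells}
    included = [c for c in sizes.index if str(c) not in excluded]
    if not included:
        raise ValueError(f"all clusters have < {min_cells} cells")
    if excluded:
        logger.info("excluding %d cluster(s) with < %d cells: %s",
                    len(excluded), min_cells, sorted(excluded))

    counts = _dense_counts(dataset[:, genes])
    labels = dataset.obs["cluster"].to_numpy()
    pct, mean, n_expr = {}, {}, {}
    for cl in included:
        mask = labels == cl
        block = counts[mask]
        n_expr[str(cl)] = (block > 0).sum(axis=0)
        pct[str(cl)] = 100.0 * n_expr[str(cl)] / block.shape[0]
        mean[str(cl)] = block.mean(axis=0)
    pct_df = pd.DataFrame(pct, index=genes)
    mean_df = pd.DataFrame(mean, index=genes)

    lo = mean_df.min(axis=1)
    span = (mean_df.max(axis=1) - lo).replace(0.0, np.nan)
    norm = mean_df.sub(lo, axis=0).div(span, axis=0).fillna(0.0)

    expr_df = pd.DataFrame(n_expr, index=genes).astype(float)
    totals = expr_df.sum(axis=1).replace(0.0, np.nan)
    rel = (100.0 * expr_df.div(totals, axis=0)).fillna(0.0)

    return ClusterSummary(
        pct_expressing=pct_df,
        mean_expression=mean_df,
        normalized_mean=norm,
        relative_pct=rel,
        excluded_clusters=excluded,
        min_cells=min_cells,
    )


def restricted_genes(
    summary: ClusterSummary,
    mean_share: float = 0.9,
    max_offtarget_pct: float = 10.0,
) -> list[str]:
    """Genes expressed essentially in a single cluster.

    A gene is flagged when its top cluster holds at least ``mean_share`` of
    the proportionally normalized mean expression and the percentage of
    expressing cells in every other cluster is at most
    ``max_offtarget_pct``.
    """
    mean = summary.mean_expression
    totals = mean.sum(axis=1)
    flagged = []
    for gene in mean.index:
        if totals[gene] <= 0:
            continue
        share = mean.loc[gene] / totals[gene]
        top = share.idxmax()
        others = [c for c in mean.columns if c != top]
        if share[top] >= mean_share and (
            summary.pct_expressing.loc[gene, others] <= max_offtarget_pct
        ).all():
            flagged.append(gene)
    return flagged
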