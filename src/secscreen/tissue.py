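"""Tissue-distribution correlation clustering.

Gene x tissue consensus profiles are min-max scaled per gene, correlated
pairwise (Pearson), and clustered hierarchically on the correlation
distance ``d = 1 - r``; the module containing the anchor genes is the
tissue-restricted module of interest. Proportional normalization (tissue
shares summing to 1) supports the companion heatmap view.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

DEFAULT_N_MODULES = 8
DEFAULT_LINKAGE = "average"


def minmax_scale(profile: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Scale each gene row to [0, 1]: ``(x - min) / (max - min)``.

    Constant rows (max == min) are mapped to all zeros and returned in the
    flagged list; non-constant rows attain both 0 and 1 exactly.
    """
    if profile.shape[1] < 2:
        raise ValueError("need at least 2 tissues to scale")
    values = profile.to_numpy(dtype=float)
    lo = values.min(axis=1, keepdims=True)
    hi = values.max(axis=1, keepdims=True)
    span = hi - lo
    constant = span[:, 0] == 0.0
    span[constant] = 1.0
    scaled = (values - lo) / span
    scaled[constant] = 0.0
    flagged = list(profile.index[constant])
    if flagged:
        logger.warning("%d constant row(s) scaled to all-zero", len(flagged))
    return pd.DataFrame(scaled, index=profile.index, columns=profile.columns), flagged


def proportional_normalize(profile: pd.DataFrame) -> pd.DataFrame:
    """Divide each gene row by its sum so tissue shares sum to 1."""
    values = profile.to_numpy(dtype=float)
    sums = values.sum(axis=1)
    zero = sums == 0.0
    if zero.any():
        bad = list(profile.index[zero])
        raise ValueError(f"all-zero row(s) cannot be normalized: {bad[:5]}")
    out = values / sums[:, None]
    return pd.DataFrame(out, index=profile.index, columns=profile.columns)


def pairwise_gene_correlation(scaled: pd.DataFrame) -> pd.DataFrame:
    """Symmetric gene x gene Pearson correlation matrix with unit diagonal.

    Rows must be non-constant (exclude constant rows upstream, e.g. the
    ones flagged by :func:`minmax_scale`).
    """
    if scaled.shape[1] < 3:
        raise ValueError("need at least 3 tissues for pairwise correlation")
    values = scaled.to_numpy(dtype=float)
    if (values.std(axis=1) == 0.0).any():
        bad = list(scaled.index[values.std(axis=1) == 0.0])
        raise ValueError(f"constant row(s) must be excluded first: {bad[:5]}")
    corr = np.corrcoef(values)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2.0
    return pd.DataFrame(corr, index=scaled.index, columns=scaled.index)


@dataclass
class ClusterModule:
    """One module from the hierarchical cut."""

    module_id: int
    genes: list[str]
    contains_anchors: bool = False
    linkage_method: str = DEFAULT_LINKAGE
    n_modules: int = DEFAULT_N_MODULES


def hierarchical_modules(
    corr: pd.DataFrame,
    n_modules: int = DEFAULT_N_MODULES,
    method: str = DEFAULT_LINKAGE,
) -> list[ClusterModule]:
    """Cut an agglomerative tree on ``d = 1 - r`` into exactly n_modules.

    Average linkage by default. Modules are renumbered by first gene
    occurrence so output ids are deterministic under fixed input.
    """
    values = corr.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1] or not np.allclose(values, values.T,
                                                             atol=1e-8):
        raise ValueError("correlation matrix must be square and symmetric")
    n = values.shape[0]
    if not 1 <= n_modules <= n:
        raise ValueError(f"n_modules must lie in [1, {n}], got {n_modules}")
    dist = 1.0 - (values + values.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    np.clip(dist, 0.0, None, out=dist)
    condensed = squareform(dist, checks=False)
    tree = linkage(condensed, method=method)
    labels = fcluster(tree, t=n_modules, criterion="maxclust")

    order: dict[int, int] = {}
    for lab in labels:
        if lab not in order:
            order[lab] = len(order) + 1
    modules: dict[int, list[str]] = {}
    for gene, lab in zip(corr.index, labels):
        modules.setdefault(order[lab], []).append(gene)
    return [
        ClusterModule(module_id=mid, genes=genes, linkage_method=method,
                      n_modules=n_modules)
        for mid, genes in sorted(modules.items())
    ]


def anchor_module(modules: list[ClusterModule],
                  anchors: list[str]) -> ClusterModule:
    """Return the module containing the anchors.

    If the anchors split across modules, the module holding the majority is
    returned with ``contains_anchors=False`` (ties go to the lower module
    id) and a warning is logged.
    """
    assigned = {g for m in modules for g in m.genes}
    missing = [a for a in anchors if a not in assigned]
    if missing:
        raise KeyError(f"anchor(s) not in clustered universe: {missing}")
    counts = [(sum(a in m.genes for a in anchors), m) for m in modules]
    best_count = max(c for c, _ in counts)
    winner = min((m for c, m in counts if c == best_count),
                 key=lambda m: m.module_id)
    together = best_count == len(anchors)
    if not together:
        logger.warning("anchors split across modules; returning majority module %d",
                       winner.module_id)
    return ClusterModule(
        module_id=winner.module_id,
        genes=list(winner.genes),
        contains_anchors=together,
        linkage_method=winner.linkage_method,
        n_modules=winner.n_modules,
    )


def cluster_profile(
    profile: pd.DataFrame,
    anchors: list[str],
    n_modules: int = DEFAULT_N_MODULES,
    method: str = DEFAULT_LINKAGE,
) -> tuple[list[ClusterModule], ClusterModule, pd.DataFrame]:
    """Scale, correlate and cluster a profile; return modules + anchor module.

    Constant rows are excluded before correlation (logged).
    """
    scaled, flagged = minmax_scale(profile)
    kept = scaled.drop(index=flagged)
    corr = pairwise_gene_correlation(kept)
    modules = hierarchical_modules(corr, n_modules=n_modules, method=method)
    return modules, anchor_module(modules, anchors), corr
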