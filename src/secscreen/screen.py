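"""Anchor-gene co-expression screen.

Genes are ranked by Pearson correlation to anchor genes (APOB/MTTP in the
original application) within each tissue; genes exceeding the correlation
threshold for every (anchor, tissue) pair form the candidate set, the
four-way intersection of the per-pair pass sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.6

TRANSFORMS = ("log2p1", "identity")


class UndefinedCorrelationError(ValueError):
    """Pearson correlation requested for a constant vector."""


def pearson_correlation(x, y) -> float:
    """Sample Pearson correlation coefficient of two vectors.

    Raises on length mismatch, fewer than 3 observations, or a constant
    input (the coefficient is undefined; it is never silently zero).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))


def _apply_transform(values: pd.DataFrame, transform: str) -> pd.DataFrame:
    if transform == "log2p1":
        return np.log2(values + 1.0)
    if transform == "identity":
        return values
    raise ValueError(f"unknown transform {transform!r}; choose from {TRANSFORMS}")


def anchor_correlations(
    matrix: pd.DataFrame,
    anchors: list[str],
    transform: str = "log2p1",
) -> pd.DataFrame:
    """Correlation of every gene with every anchor in one tissue.

    ``matrix`` is genes x samples. Correlations are computed on
    ``log2(x+1)``-transformed values by default (``transform='identity'``
    for the raw scale). Constant genes get NaN (their count is logged);
    each anchor's self-correlation is reported as 1.0.
    """
    missing = [a for a in anchors if a not in matrix.index]
    if missing:
        raise KeyError(f"anchor gene(s) not in matrix: {missing}")
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples per tissue")
    values = _apply_transform(matrix.astype(float), transform)

    x = values.to_numpy()
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1)
    constant = norms == 0.0
    n_constant = int(constant.sum())
    if n_constant:
        logger.warning("%d constant gene(s) have undefined correlation "
                       "and are reported as missing", n_constant)
    anchor_idx = [matrix.index.get_loc(a) for a in anchors]
    if any(constant[i] for i in anchor_idx):
        bad = [a for a, i in zip(anchors, anchor_idx) if constant[i]]
        raise UndefinedCorrelationError(f"anchor(s) constant across samples: {bad}")

    safe = np.where(constant, 1.0, norms)
    with np.errstate(invalid="ignore"):
        r = (xc @ xc[anchor_idx].T) / np.outer(safe, norms[anchor_idx])
    r[constant] = np.nan
    np.clip(r, -1.0, 1.0, out=r)
    for j, i in enumerate(anchor_idx):
        r[i, j] = 1.0  # self-correlation, flagged below
    table = pd.DataFrame(r, index=matrix.index, columns=list(anchors))
    table.attrs["self_anchors"] = list(anchors)
    table.attrs["n_constant"] = n_constant
    return table


@dataclass
class AnchorScreenResult:
    """Outcome of the four-way thresholded intersection.

    ``r_table`` has one ``tissue:anchor`` column per pair; ``passes`` the
    corresponding booleans (strict ``r > threshold``); ``candidate_set``
    the genes passing every pair, anchors excluded; ``ranking`` those genes
    in descending order of their minimum r across pairs; ``venn_counts``
    the 15 non-empty region sizes of the 4-set Venn diagram.
    """

    r_table: pd.DataFrame
    passes: pd.DataFrame
    candidate_set: list[str]
    ranking: pd.DataFrame
    threshold: float
    anchors: list[str]
    venn_counts: dict[str, int] = field(default_factory=dict)

    @property
    def pair_counts(self) -> pd.Series:
        return self.passes.sum(axis=0)


def candidate_intersection(
    tables: dict[str, pd.DataFrame],
    threshold: float = DEFAULT_THRESHOLD,
) -> AnchorScreenResult:
    """Intersect per-tissue anchor-correlation tables at a threshold.

    ``tables`` maps tissue label to the frame from
    :func:`anchor_correlations` (same anchors in each). A gene is a
    candidate when ``r > threshold`` for every (anchor, tissue) pair; the
    anchors themselves are excluded. Genes absent from any tissue (or with
    undefined correlation) cannot pass; the screen operates on the
    intersection of the tissue gene universes.
    """
    if not -1.0 <= threshold < 1.0:
        raise ValueError(f"threshold must lie in [-1, 1), got {threshold}")
    if len(tables) < 2:
        raise ValueError("need at least two tissues")
    universes = [set(t.index) for t in tables.values()]
    shared = sorted(set.intersection(*universes))
    if not shared:
        raise ValueError("tissue gene universes are disjoint")
    n_dropped = len(set.union(*universes)) - len(shared)
    if n_dropped:
        logger.warning("%d gene(s) absent from some tissue dropped from screen",
                       n_dropped)

    anchors: list[str] = list(next(iter(tables.values())).columns)
    cols = {}
    for tissue, table in tables.items():
        if list(table.columns) != anchors:
            raise ValueError("anchor sets differ between tissues")
        for anchor in anchors:
            cols[f"{tissue}:{anchor}"] = table.loc[shared, anchor]
    r_table = pd.DataFrame(cols, index=pd.Index(shared, name="gene_id"))
    passes = r_table.gt(threshold) & r_table.notna()

    is_anchor = r_table.index.isin(anchors)
    all_pass = passes.all(axis=1) & ~is_anchor
    candidates = list(r_table.index[all_pass])

    min_r = r_table.min(axis=1)
    ranking = (
        pd.DataFrame({"min_r": min_r[candidates]})
        .join(r_table.loc[candidates])
        .sort_values(["min_r"], ascending=False, kind="stable")
    )
    order = sorted(ranking.index, key=lambda gid: (-ranking.at[gid, "min_r"], gid))
    ranking = ranking.loc[order]

    venn: dict[str, int] = {}
    pair_names = list(passes.columns)
    member = passes[~is_anchor]
    for k in range(1, len(pair_names) + 1):
        for combo in combinations(pair_names, k):
            in_combo = member[list(combo)].all(axis=1)
            out_combo = member[[p for p in pair_names if p not in combo]]
            exact = in_combo & ~out_combo.any(axis=1) if len(combo) < len(
                pair_names) else in_combo
            venn["&".join(combo)] = int(exact.sum())

    return AnchorScreenResult(
        r_table=r_table,
        passes=passes,
        candidate_set=candidates,
        ranking=ranking,
        threshold=threshold,
        anchors=anchors,
        venn_counts=venn,
    )


def rank_candidates(result: AnchorScreenResult) -> list[str]:
    """Candidates ordered by descending minimum r, ties by gene id."""
    return list(result.ranking.index)


def run_screen(
    matrices: dict[str, pd.DataFrame],
    anchors: list[str],
    threshold: float = DEFAULT_THRESHOLD,
    transform: str = "log2p1",
) -> AnchorScreenResult:
    """Convenience wrapper: correlations per tissue, then intersection."""
    tables = {
        tissue: anchor_correlations(matrix, anchors, transform=transform)
        for tissue, matrix in matrices.items()
    }
    return candidate_intersection(tables, threshold=threshold)
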