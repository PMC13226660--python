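"""Genotype-dependent fasting/refeeding response classification.

Per gene, the refeeding-vs-fasting response is the log2 fold change of
mean expression (refeeding over fasting, with a pseudocount) computed
separately in control and knockout genotypes. Genes with a greater than
twofold control response are "responsive"; among them, a greater than
twofold difference between the knockout and control responses classifies
the gene as blunted (knockout response shrunk toward, or past, zero) or
enhanced (amplified). Over-representation of gene sets among a selection
is tested with the exact hypergeometric tail and Benjamini-Hochberg
adjustment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENOTYPES = ("CTL", "KO")
CONDITIONS = ("fasting", "refeeding")
STATUSES = ("not_responsive", "concordant", "blunted", "enhanced")

DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_RESP_THRESH = 1.0  # log2: the >twofold responsive gate
DEFAULT_DIFF_THRESH = 1.0  # log2: the twofold-difference diagonal


def parse_sample_columns(columns: list[str]) -> pd.DataFrame:
    """Parse ``GENOTYPE_condition_repN`` sample names into a factor table."""
    rows = []
    for col in columns:
        parts = col.split("_")
        if len(parts) != 3 or parts[0] not in GENOTYPES or parts[1] not in CONDITIONS:
            raise ValueError(
                f"sample column {col!r} does not match GENOTYPE_condition_repN"
            )
        rows.append({"sample": col, "genotype": parts[0], "condition": parts[1],
                     "replicate": parts[2]})
    return pd.DataFrame(rows).set_index("sample")


def condition_means(dataset: pd.DataFrame) -> pd.DataFrame:
    """Mean expression per gene for each genotype x condition cell.

    Columns of the result are a (genotype, condition) MultiIndex. Every
    cell must have at least one replicate; single-replicate cells are
    allowed with a logged warning.
    """
    factors = parse_sample_columns(list(dataset.columns))
    means = {}
    for geno in GENOTYPES:
        for cond in CONDITIONS:
            cols = factors.index[(factors["genotype"] == geno)
                                 & (factors["condition"] == cond)]
            if len(cols) == 0:
                raise ValueError(f"no replicate for cell {geno}/{cond}")
            if len(cols) == 1:
                logger.warning("cell %s/%s has a single replicate", geno, cond)
            means[(geno, cond)] = dataset[cols].mean(axis=1)
    out = pd.DataFrame(means)
    out.columns = pd.MultiIndex.from_tuples(out.columns,
                                            names=["genotype", "condition"])
    return out


def log2_response(means: pd.DataFrame,
                  pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Per-genotype log2((refed + c) / (fast + c)); columns CTL, KO."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    out = {}
    for geno in GENOTYPES:
        num = means[(geno, "refeeding")] + pseudocount
        den = means[(geno, "fasting")] + pseudocount
        out[geno] = np.log2(num / den)
    return pd.DataFrame(out)


def classify_response(
    log2fc_ctl: float,
    log2fc_ko: float,
    resp_thresh: float = DEFAULT_RESP_THRESH,
    diff_thresh: float = DEFAULT_DIFF_THRESH,
) -> tuple[str, bool]:
    """Classify one gene's genotype-dependent refeeding response.

    Not responsive when ``|log2FC_CTL| <= resp_thresh``. Otherwise the
    knockout response is projected onto the control direction
    (``p = sign(log2FC_CTL) * log2FC_KO``) and compared with the control
    magnitude: ``delta = p - |log2FC_CTL|``. ``|delta| <= diff_thresh`` is
    concordant; ``delta < -diff_thresh`` blunted; ``delta > diff_thresh``
    enhanced. ``reversed_flag`` marks knockouts responding in the opposite
    direction (p < 0), which under this geometry co-occurs with blunting.
    """
    if resp_thresh <= 0 or diff_thresh <= 0:
        raise ValueError("thresholds must be positive")
    if not (math.isfinite(log2fc_ctl) and math.isfinite(log2fc_ko)):
        raise ValueError("log2 fold changes must be finite")
    if abs(log2fc_ctl) <= resp_thresh:
        return "not_responsive", False
    direction = 1.0 if log2fc_ctl > 0 else -1.0
    projected = direction * log2fc_ko
    delta = projected - abs(log2fc_ctl)
    if delta < -diff_thresh:
        status = "blunted"
    elif delta > diff_thresh:
        status = "enhanced"
    else:
        status = "concordant"
    return status, projected < 0


def classify_table(
    means: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    resp_thresh: float = DEFAULT_RESP_THRESH,
    diff_thresh: float = DEFAULT_DIFF_THRESH,
) -> pd.DataFrame:
    """Vectorized classification of every gene from condition means."""
    log2fc = log2_response(means, pseudocount=pseudocount)
    ctl = log2fc["CTL"].to_numpy()
    ko = log2fc["KO"].to_numpy()
    if not np.isfinite(ctl).all() or not np.isfinite(ko).all():
        raise ValueError("non-finite fold change encountered")
    direction = np.where(ctl >= 0, 1.0, -1.0)
    projected = direction * ko
    delta = projected - np.abs(ctl)
    status = np.full(len(ctl), "concordant", dtype=object)
    status[delta < -diff_thresh] = "blunted"
    status[delta > diff_thresh] = "enhanced"
    responsive = np.abs(ctl) > resp_thresh
    status[~responsive] = "not_responsive"
    out = pd.DataFrame(
        {
            "mean_fast_CTL": means[("CTL", "fasting")],
            "mean_refed_CTL": means[("CTL", "refeeding")],
            "mean_fast_KO": means[("KO", "fasting")],
            "mean_refed_KO": means[("KO", "refeeding")],
            "log2FC_CTL": ctl,
            "log2FC_KO": ko,
            "delta": delta,
            "status": status,
            "reversed_flag": responsive & (projected < 0),
        },
        index=means.index,
    )
    out.attrs.update(resp_thresh=resp_thresh, diff_thresh=diff_thresh,
                     pseudocount=pseudocount)
    return out


def summarize_classes(classification: pd.DataFrame) -> dict:
    """Status counts plus the blunted share of altered (blunted+enhanced)."""
    if classification.empty:
        raise ValueError("classification table is empty")
    counts = {s: int((classification["status"] == s).sum()) for s in STATUSES}
    altered = counts["blunted"] + counts["enhanced"]
    responsive = altered + counts["concordant"]
    return {
        "counts": counts,
        "n_genes": int(len(classification)),
        "n_responsive": responsive,
        "n_altered": altered,
        "blunted_fraction": counts["blunted"] / altered if altered else None,
        "n_reversed": int(classification["reversed_flag"].sum()),
    }


@dataclass
class EnrichmentResult:
    """Hypergeometric over-representation of one gene set."""

    set_id: str
    k: int  # overlap
    n: int  # selection size
    K: int  # set size within universe
    N: int  # universe size
    p_value: float
    p_adjusted: float | None = None


def hypergeometric_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by exact summation."""
    if N <= 0:
        raise ValueError("universe must be non-empty")
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k):
        raise ValueError("invalid hypergeometric parameters")
    hi = min(n, K)
    if k > hi:
        return 0.0
    total = math.comb(N, n)
    acc = 0
    for i in range(max(k, 0), hi + 1):
        acc += math.comb(K, i) * math.comb(N - K, n - i)
    return acc / total


def hypergeometric_enrichment(
    selected: set[str],
    gene_set: set[str],
    universe: set[str],
    set_id: str = "",
) -> EnrichmentResult:
    """Over-representation of ``gene_set`` within ``selected``.

    ``selected`` must be a subset of ``universe``; the gene set is
    intersected with the universe first.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    selected = set(selected)
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    members = set(gene_set) & universe
    k = len(selected & members)
    p = hypergeometric_tail(k, len(universe), len(members), len(selected))
    return EnrichmentResult(set_id=set_id, k=k, n=len(selected),
                            K=len(members), N=len(universe), p_value=p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def enrich_gene_sets(
    selected: set[str],
    gene_sets: dict[str, list[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric enrichment of every set, BH-adjusted, sorted by p_adj."""
    results = [
        hypergeometric_enrichment(selected, set(members), universe, set_id=name)
        for name, members in gene_sets.items()
    ]
    table = pd.DataFrame(
        {
            "set_id": [r.set_id for r in results],
            "k": [r.k for r in results],
            "K": [r.K for r in results],
            "n": [r.n for r in results],
            "N": [r.N for r in results],
            "p_value": [r.p_value for r in results],
        }
    ).set_index("set_id")
    table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy())
    return table.sort_values(["p_adjusted", "p_value", "set_id"],
                             kind="stable")
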