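"""Synthetic study generators with planted ground truth.

Four generators emulate the four data shapes consumed by the pipeline:

* :func:`gen_coexpression_tissues` — bulk genes x samples matrices for two
  tissues, with a latent one-factor co-expression module planted in both
  tissues (containing the two anchor genes), a second module restricted to
  tissue A, and independent background genes.
* :func:`gen_tissue_profiles` — a gene x tissue consensus profile with
  genes restricted to the designated liver/intestine pair, decoy groups
  restricted to other tissue pairs, and broadly expressed genes.
* :func:`gen_single_cell` — labelled negative-binomial counts with genes
  restricted to the hepatocyte cluster, including one tiny (< 10 cells)
  cluster to exercise the exclusion filter.
* :func:`gen_response_dataset` — a two-genotype x two-condition expression
  table in which planted responsive genes have their refeeding response
  blunted or enhanced in the knockout, plus GMT gene sets with one set
  enriched among blunted genes.

Every generator is a pure function of a :class:`~secscreen.config.SimConfig`;
fixing the seed makes outputs bit-identical. Each returns a
:class:`SyntheticTruth` carrying one planted class per gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from secscreen.config import SimConfig, SimConfigError

# planted_class vocabulary
BOTH_TISSUE = "both_tissue_module"
SINGLE_TISSUE = "single_tissue_module"
BACKGROUND = "background"
TISSUE_RESTRICTED = "tissue_restricted"
BROAD = "broad"
CELLTYPE_RESTRICTED = "celltype_restricted"
RESP_CONCORDANT = "responsive_concordant"
RESP_BLUNTED = "responsive_blunted"
RESP_ENHANCED = "responsive_enhanced"
NULL = "null"

#: cluster names used for the single-cell simulation; cluster 0 is the
#: hepatocyte analogue, the final name is reserved for the tiny cluster.
_CLUSTER_NAMES = ["hepatocytes", "endothelial", "kupffer", "stellate",
                  "neutrophils", "tcells", "bcells", "dendritic"]

_STREAM = {"coexpr": 11, "profile": 12, "single_cell": 13, "response": 14}


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    # independent, reproducible stream per generator
    return np.random.default_rng([_STREAM[stream], config.seed])


def gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


@dataclass
class SyntheticTruth:
    """Planted labels for one generated dataset.

    ``table`` is indexed by gene id with a ``planted_class`` column (one
    class per gene) and, where relevant, a ``module_label`` column naming
    the planted group a gene belongs to.
    """

    table: pd.DataFrame
    anchor_ids: list[str]
    config: SimConfig

    def genes_with(self, planted_class: str) -> list[str]:
        mask = self.table["planted_class"] == planted_class
        return list(self.table.index[mask])

    def class_counts(self) -> pd.Series:
        return self.table["planted_class"].value_counts()

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["is_anchor"] = out.index.isin(self.anchor_ids)
        return out


def _truth(classes: pd.Series, anchors: list[str], config: SimConfig,
           module_label: pd.Series | None = None) -> SyntheticTruth:
    table = pd.DataFrame({"planted_class": classes})
    if module_label is not None:
        table["module_label"] = module_label
    table.index.name = "gene_id"
    return SyntheticTruth(table=table, anchor_ids=anchors, config=config)


# ---------------------------------------------------------------------------
# bulk co-expression
# ---------------------------------------------------------------------------

def within_module_correlation(config: SimConfig) -> float:
    """Analytic within-module Pearson correlation of the one-factor model."""
    lam2 = config.module_loading**2
    return lam2 / (lam2 + config.noise_sd**2)


def gen_coexpression_tissues(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate bulk expression for two tissues with planted modules.

    Module genes follow a one-factor Gaussian model per tissue:
    ``x = baseline + loading * factor_sample + noise``; the both-tissue
    module (anchors first) loads in both tissues on tissue-specific
    factors, the single-tissue module loads in tissue A only, and
    background genes are independent noise with matched marginal variance.
    Values are clipped at zero.

    Returns ``(tissue_A, tissue_B, truth)`` with genes x samples frames.
    """
    if config.module_size < 3:
        raise SimConfigError("module_size must be >= 3 (two anchors + one gene)")
    if 2 * config.module_size > config.n_genes:
        raise SimConfigError("n_genes too small for two planted modules")
    rng = _rng(config, "coexpr")
    n, m = config.n_genes, config.n_samples_per_tissue
    ids = gene_ids(n)
    both = np.arange(config.module_size)
    single = np.arange(config.module_size, 2 * config.module_size)

    # matched marginal s.d. for genes without a factor
    total_sd = np.hypot(config.module_loading, config.noise_sd)
    matrices = []
    for tissue_idx, tissue in enumerate(("tissueA", "tissueB")):
        x = config.base_expression_scale + total_sd * rng.standard_normal((n, m))
        factor_both = rng.standard_normal(m)
        x[both] = (
            config.base_expression_scale
            + config.module_loading * factor_both
            + config.noise_sd * rng.standard_normal((len(both), m))
        )
        if tissue_idx == 0:
            factor_single = rng.standard_normal(m)
            x[single] = (
                config.base_expression_scale
                + config.module_loading * factor_single
                + config.noise_sd * rng.standard_normal((len(single), m))
            )
        np.clip(x, 0.0, None, out=x)
        samples = [f"{tissue}_s{j:03d}" for j in range(m)]
        matrices.append(pd.DataFrame(x, index=ids, columns=samples))

    classes = pd.Series(BACKGROUND, index=ids)
    classes.iloc[both] = BOTH_TISSUE
    classes.iloc[single] = SINGLE_TISSUE
    anchors = [ids[0], ids[1]]
    return matrices[0], matrices[1], _truth(classes, anchors, config)


# ---------------------------------------------------------------------------
# tissue profiles
# ---------------------------------------------------------------------------

def gen_tissue_profiles(config: SimConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a gene x tissue consensus profile (nTPM-like).

    The designated pair is the first two tissues (liver/intestine
    analogues): ``tissue_restricted`` genes — the planted co-expression
    module, anchors included — express high in exactly those two tissues
    and near zero elsewhere. ``n_decoy_groups`` groups of the same size are
    restricted to other disjoint tissue pairs (class ``background``, group
    recorded in ``module_label``), giving a multi-block structure for
    module-recovery tests. ``broad`` genes express comparably everywhere.
    """
    if config.n_tissues < 3:
        raise SimConfigError("n_tissues must be >= 3")
    needed = 2 + 2 * config.n_decoy_groups
    if config.n_tissues < needed:
        raise SimConfigError(
            f"n_tissues={config.n_tissues} too small for {config.n_decoy_groups} "
            f"decoy pairs (needs >= {needed})"
        )
    rng = _rng(config, "profile")
    g = config.module_size
    groups = 1 + config.n_decoy_groups
    n_prof = groups * g + config.n_broad
    ids = gene_ids(groups * g)[:]  # restricted groups reuse the module ids
    ids = ids + [f"b{i:05d}" for i in range(config.n_broad)]

    tissues = ["liver", "intestine"] + [
        f"tissue_{i:02d}" for i in range(2, config.n_tissues)
    ]
    high = 50.0 * config.base_expression_scale
    values = np.zeros((n_prof, config.n_tissues))
    classes = pd.Series(BROAD, index=ids)
    labels = pd.Series("broad", index=ids)

    for grp in range(groups):
        rows = slice(grp * g, (grp + 1) * g)
        pair = (2 * grp, 2 * grp + 1)
        noise = rng.standard_normal((g, config.n_tissues))
        # off-target leakage scales with the noise s.d. so the noise-free
        # limit is exactly zero outside the designated pair
        values[rows] = high * config.profile_noise_sd * np.abs(noise) * 0.2
        for t in pair:
            values[rows, t] = high * (
                1.0 + config.profile_noise_sd * rng.standard_normal(g)
            )
        label = "designated" if grp == 0 else f"decoy_{grp}"
        classes.iloc[rows] = TISSUE_RESTRICTED if grp == 0 else BACKGROUND
        labels.iloc[rows] = label

    level = 3.0 * config.base_expression_scale * rng.lognormal(0.0, 0.3, config.n_broad)
    broad_rows = slice(groups * g, n_prof)
    values[broad_rows] = level[:, None] * (
        1.0 + config.profile_noise_sd
        * rng.standard_normal((config.n_broad, config.n_tissues))
    )
    np.clip(values, 0.0, None, out=values)

    profile = pd.DataFrame(values, index=ids, columns=tissues)
    anchors = ids[:2]
    return profile, _truth(classes, anchors, config, module_label=labels)


# ---------------------------------------------------------------------------
# single cell
# ---------------------------------------------------------------------------

def _nb_counts(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Negative-binomial draws parameterised by (mean, dispersion).

    ``var = mean + mean^2 / dispersion``; a zero mean yields zero counts.
    """
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def gen_single_cell(config: SimConfig) -> tuple[ad.AnnData, SyntheticTruth]:
    """Simulate labelled single-cell counts (cells x genes AnnData).

    ``celltype_restricted`` genes — the planted co-expression module — have
    elevated negative-binomial means only in cluster 0 (hepatocytes);
    ``broad`` genes are elevated in every cluster; background genes are
    lowly expressed everywhere. Exactly one cluster must have < 10 cells so
    downstream small-cluster exclusion is exercised.
    """
    sizes = list(config.n_cells_per_cluster)
    if len(sizes) < 2:
        raise SimConfigError("need at least 2 single-cell clusters")
    if sum(1 for s in sizes if s < 10) != 1:
        raise SimConfigError("exactly one cluster must have < 10 cells")
    rng = _rng(config, "single_cell")

    g = config.module_size
    restricted_ids = gene_ids(g)
    broad_ids = [f"b{i:05d}" for i in range(config.n_broad)]
    bg_ids = [f"n{i:05d}" for i in range(config.n_sc_background)]
    ids = restricted_ids + broad_ids + bg_ids
    n_genes = len(ids)

    names = list(_CLUSTER_NAMES)
    while len(names) < len(sizes):
        names.append(f"cluster_{len(names)}")
    # the tiny cluster keeps a fixed, recognisable name
    small_idx = next(i for i, s in enumerate(sizes) if s < 10)
    cluster_names = [names[i] for i in range(len(sizes))]
    if small_idx != len(sizes) - 1:
        cluster_names[small_idx] = "neutrophils"

    mean = np.zeros((len(sizes), n_genes))
    mean[:, :g] = 0.05
    mean[0, :g] = 5.0
    mean[:, g:g + config.n_broad] = 2.0
    mean[:, g + config.n_broad:] = 0.2

    blocks, clusters = [], []
    for k, size in enumerate(sizes):
        blocks.append(_nb_counts(rng, np.broadcast_to(mean[k], (size, n_genes)),
                                 config.nb_dispersion))
        clusters.extend([cluster_names[k]] * size)
    counts = np.vstack(blocks)
    cells = [f"c{i:05d}" for i in range(counts.shape[0])]

    adata = ad.AnnData(
        X=sparse.csr_matrix(counts.astype(np.int32)),
        obs=pd.DataFrame({"cluster": pd.Categorical(clusters)},
                         index=pd.Index(cells, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(ids, name="gene_id")),
    )
    classes = pd.Series(NULL, index=ids)
    classes.iloc[:g] = CELLTYPE_RESTRICTED
    classes.iloc[g:g + config.n_broad] = BROAD
    return adata, _truth(classes, ids[:2], config)


# ---------------------------------------------------------------------------
# fasting/refeeding response
# ---------------------------------------------------------------------------

def gen_response_dataset(
    config: SimConfig,
) -> tuple[pd.DataFrame, dict[str, list[str]], SyntheticTruth]:
    """Simulate a two-genotype fasting/refeeding expression table plus GMT sets.

    Responsive genes receive a control-genotype refeeding response
    ``|log2 refed/fast| in [1.5, 3.5]``. A planted ``blunted_fraction`` of
    them have the knockout response shrunk (possibly reversed) so the
    genotype difference exceeds the twofold line by a [1.2, 3] log2 margin;
    an ``enhanced_fraction`` are amplified likewise; the remainder respond
    concordantly. Null genes have no condition effect.

    Means are constructed so that with the default pseudocount of 1 the
    classifier's fold changes equal the planted values exactly in the
    noise-free limit. Gene sets: one "lipid_biosynthesis" set composed 80%
    of planted blunted genes, plus four decoy sets drawn from null genes.
    """
    rng = _rng(config, "response")
    n = config.n_genes
    ids = gene_ids(n)
    n_resp = config.n_responsive
    n_blunt = int(round(config.blunted_fraction * n_resp))
    n_enh = int(round(config.enhanced_fraction * n_resp))
    if n_blunt + n_enh > n_resp:
        n_enh = n_resp - n_blunt

    classes = pd.Series(NULL, index=ids)
    classes.iloc[:n_blunt] = RESP_BLUNTED
    classes.iloc[n_blunt:n_blunt + n_enh] = RESP_ENHANCED
    classes.iloc[n_blunt + n_enh:n_resp] = RESP_CONCORDANT

    l_ctl = np.zeros(n)
    l_ko = np.zeros(n)
    if n_resp:
        mag = rng.uniform(1.5, 3.5, n_resp)
        sign = rng.choice([-1.0, 1.0], n_resp)
        l_ctl[:n_resp] = sign * mag
        l_ko[:n_resp] = l_ctl[:n_resp]
        delta = rng.uniform(1.2, 3.0, n_resp)
        l_ko[:n_blunt] -= sign[:n_blunt] * delta[:n_blunt]
        l_ko[n_blunt:n_blunt + n_enh] += (
            sign[n_blunt:n_blunt + n_enh] * delta[n_blunt:n_blunt + n_enh]
        )

    # fasting mean floored so refed means stay positive after the +1
    # pseudocount identity m_refed = (m_fast + 1) * 2**L - 1
    floor = np.power(2.0, np.maximum(0.0, -np.minimum(l_ctl, l_ko)))
    m_fast = floor * rng.uniform(5.0, 50.0, n)
    means = {
        ("CTL", "fasting"): m_fast,
        ("CTL", "refeeding"): (m_fast + 1.0) * np.power(2.0, l_ctl) - 1.0,
        ("KO", "fasting"): m_fast,
        ("KO", "refeeding"): (m_fast + 1.0) * np.power(2.0, l_ko) - 1.0,
    }

    sigma = config.response_noise_sd
    columns: dict[str, np.ndarray] = {}
    for (geno, cond), mu in means.items():
        for rep in range(1, config.n_replicates + 1):
            noise = rng.standard_normal(n)
            # mean-one multiplicative log-normal noise
            vals = mu * np.exp(sigma * noise - 0.5 * sigma**2)
            columns[f"{geno}_{cond}_rep{rep}"] = np.clip(vals, 0.0, None)
    table = pd.DataFrame(columns, index=ids)

    gene_sets = _response_gene_sets(rng, classes)
    return table, gene_sets, _truth(classes, [], config)


def _response_gene_sets(rng: np.random.Generator,
                        classes: pd.Series) -> dict[str, list[str]]:
    blunted = classes.index[classes == RESP_BLUNTED].to_numpy()
    nulls = classes.index[classes == NULL].to_numpy()
    set_size = 40
    n_from_blunted = min(int(round(0.8 * set_size)), len(blunted))
    members = list(rng.choice(blunted, n_from_blunted, replace=False)) if \
        n_from_blunted else []
    n_fill = min(set_size - n_from_blunted, len(nulls))
    fill = list(rng.choice(nulls, n_fill, replace=False))
    sets = {"lipid_biosynthesis": sorted(members + fill)}
    for k in range(1, 5):
        size = min(set_size, len(nulls))
        sets[f"decoy_pathway_{k}"] = sorted(rng.choice(nulls, size, replace=False))
    return sets


# ---------------------------------------------------------------------------
# whole study
# ---------------------------------------------------------------------------

def simulate_study(config: SimConfig) -> dict:
    """Generate every dataset of the synthetic study on one gene universe.

    The planted co-expression module genes double as the
    liver/intestine-restricted genes of the tissue profile and the
    hepatocyte-restricted genes of the single-cell dataset, mirroring the
    evidence chain the pipeline joins. Returns a dict with keys
    ``tissue_a``, ``tissue_b``, ``profile``, ``single_cell``, ``response``,
    ``gene_sets`` and per-dataset truths under ``truth``.
    """
    tissue_a, tissue_b, truth_coexpr = gen_coexpression_tissues(config)
    profile, truth_profile = gen_tissue_profiles(config)
    adata, truth_sc = gen_single_cell(config)
    response, gene_sets, truth_resp = gen_response_dataset(config)
    # 11-gene signature over the hepatocyte-restricted module, mirroring the
    # COPII signature scored on the single-cell data
    restricted = truth_sc.genes_with(CELLTYPE_RESTRICTED)
    gene_sets = {"hepatocyte_signature": restricted[:11], **gene_sets}
    return {
        "tissue_a": tissue_a,
        "tissue_b": tissue_b,
        "profile": profile,
        "single_cell": adata,
        "response": response,
        "gene_sets": gene_sets,
        "anchors": truth_coexpr.anchor_ids,
        "truth": {
            "coexpression": truth_coexpr,
            "profile": truth_profile,
            "single_cell": truth_sc,
            "response": truth_resp,
        },
    }
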