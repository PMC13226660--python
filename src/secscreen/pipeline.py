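"""End-to-end orchestration and the joined candidate report.

The pipeline runs the four analysis stages on files produced by the
simulator (or supplied by the user), writes each stage's artifacts under
the output directory, and joins the per-gene evidence into a single
candidate report: a final hit must pass the co-expression screen, sit in
the anchor-containing tissue module, and be cluster-restricted in the
single-cell data — the evidence chain that singled out SEC16B.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from secscreen import __version__, celltype, io, response, screen, tissue
from secscreen.config import SimConfig
from secscreen.simulate import simulate_study

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and stage parameters for one end-to-end run."""

    tissue_a: str
    tissue_b: str
    profile: str
    sc_mtx: str
    sc_genes: str
    sc_cells: str
    response_table: str
    gmt: str
    outdir: str
    anchors: list[str] = field(default_factory=list)
    threshold: float = screen.DEFAULT_THRESHOLD
    transform: str = "log2p1"
    n_modules: int = tissue.DEFAULT_N_MODULES
    linkage: str = tissue.DEFAULT_LINKAGE
    top_fraction: float = celltype.DEFAULT_TOP_FRACTION
    min_cells: int = celltype.DEFAULT_MIN_CELLS
    pseudocount: float = response.DEFAULT_PSEUDOCOUNT
    resp_thresh: float = response.DEFAULT_RESP_THRESH
    diff_thresh: float = response.DEFAULT_DIFF_THRESH
    seed: int = 0

    def validate(self) -> None:
        missing = [
            p for p in (self.tissue_a, self.tissue_b, self.profile, self.sc_mtx,
                        self.sc_genes, self.sc_cells, self.response_table,
                        self.gmt)
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")
        if len(self.anchors) < 2:
            raise ValueError("need at least two anchor genes")

    def content_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded, so the same
        configuration reproduces the same hash wherever it is run)."""
        payload = dataclasses.asdict(self)
        for key in ("tissue_a", "tissue_b", "profile", "sc_mtx", "sc_genes",
                    "sc_cells", "response_table", "gmt", "outdir"):
            payload.pop(key)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Run screen, tissue clustering, cell-type scoring and response
    classification; write stage artifacts and the joined report.

    Returns the per-gene candidate report (also written to
    ``outdir/report.tsv`` with a JSON provenance sidecar).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- stage 1: anchor co-expression screen -----------------------------
    matrices = {
        "liver": io.read_expression_tsv(config.tissue_a),
        "intestine": io.read_expression_tsv(config.tissue_b),
    }
    result = screen.run_screen(matrices, config.anchors,
                               threshold=config.threshold,
                               transform=config.transform)
    sdir = outdir / "screen"
    sdir.mkdir(exist_ok=True)
    io.write_expression_tsv(result.r_table, sdir / "correlations.tsv")
    pd.Series(result.venn_counts, name="count").rename_axis("region").to_csv(
        sdir / "venn_summary.tsv", sep="\t")
    io.write_expression_tsv(result.ranking, sdir / "candidates.tsv")

    # --- stage 2: tissue-distribution clustering --------------------------
    profile = io.read_expression_tsv(config.profile)
    present = [a for a in config.anchors if a in profile.index]
    if len(present) < len(config.anchors):
        raise KeyError(f"anchor(s) missing from profile: "
                       f"{sorted(set(config.anchors) - set(present))}")
    modules, anchor_mod, corr = tissue.cluster_profile(
        profile, config.anchors, n_modules=config.n_modules,
        method=config.linkage)
    tdir = outdir / "tissue"
    tdir.mkdir(exist_ok=True)
    scaled, _ = tissue.minmax_scale(profile)
    io.write_expression_tsv(scaled, tdir / "scaled.tsv")
    io.write_expression_tsv(
        tissue.proportional_normalize(
            profile[profile.sum(axis=1) > 0]), tdir / "proportional.tsv")
    io.write_expression_tsv(corr, tdir / "correlation.tsv")
    membership = pd.DataFrame(
        [(g, m.module_id) for m in modules for g in m.genes],
        columns=["gene_id", "module_id"],
    ).set_index("gene_id")
    membership.to_csv(tdir / "modules.tsv", sep="\t")

    # --- stage 3: single-cell scoring --------------------------------------
    adata = io.read_single_cell(config.sc_mtx, config.sc_genes, config.sc_cells)
    gene_sets = io.read_gmt(config.gmt)
    scores = celltype.score_gene_sets(adata, gene_sets,
                                      top_fraction=config.top_fraction)
    summary = celltype.cluster_summary(adata, min_cells=config.min_cells)
    restricted = set(celltype.restricted_genes(summary))
    cdir = outdir / "celltype"
    cdir.mkdir(exist_ok=True)
    per_cell = pd.DataFrame({sid: s.auc for sid, s in scores.items()})
    io.write_expression_tsv(per_cell, cdir / "set_scores.tsv",
                            index_label="cell_id")
    cluster_means = pd.DataFrame({sid: s.cluster_mean for sid, s in
                                  scores.items()})
    io.write_expression_tsv(cluster_means, cdir / "set_scores_by_cluster.tsv",
                            index_label="cluster")
    dot = pd.concat(
        {"pct_expressing": summary.pct_expressing,
         "normalized_mean": summary.normalized_mean},
        axis=1,
    )
    dot.columns = [f"{stat}:{cl}" for stat, cl in dot.columns]
    io.write_expression_tsv(dot, cdir / "cluster_summary.tsv")
    pd.Series(summary.excluded_clusters, name="n_cells", dtype=int).rename_axis(
        "cluster").to_csv(cdir / "excluded_clusters.tsv", sep="\t")

    # --- stage 4: response classification + enrichment ---------------------
    resp_table = io.read_expression_tsv(config.response_table)
    means = response.condition_means(resp_table)
    classification = response.classify_table(
        means, pseudocount=config.pseudocount,
        resp_thresh=config.resp_thresh, diff_thresh=config.diff_thresh)
    class_summary = response.summarize_classes(classification)
    # universe: genes expressed in at least one sample
    universe = set(resp_table.index[(resp_table > 0).any(axis=1)])
    blunted = set(classification.index[classification["status"] == "blunted"])
    blunted &= universe
    enrichment = response.enrich_gene_sets(blunted, gene_sets, universe)
    rdir = outdir / "response"
    rdir.mkdir(exist_ok=True)
    io.write_expression_tsv(classification, rdir / "classification.tsv")
    enrichment.to_csv(rdir / "enrichment.tsv", sep="\t",
                      float_format=io.FLOAT_FORMAT)
    with open(rdir / "summary.json", "w") as fh:
        json.dump(class_summary, fh, indent=2, sort_keys=True)

    # --- join -------------------------------------------------------------
    report = result.r_table.copy()
    report["min_r"] = report.min(axis=1)
    report["candidate"] = report.index.isin(result.candidate_set)
    report = report.join(membership, how="left")
    report["in_anchor_module"] = report.index.isin(anchor_mod.genes)
    report["celltype_restricted"] = report.index.isin(restricted)
    report["response_status"] = classification["status"].reindex(report.index)
    report["final_hit"] = (report["candidate"] & report["in_anchor_module"]
                           & report["celltype_restricted"])
    io.write_expression_tsv(report, outdir / "report.tsv")

    provenance = {
        "version": __version__,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_candidates": len(result.candidate_set),
        "n_final_hits": int(report["final_hit"].sum()),
        "anchor_module_size": len(anchor_mod.genes),
        "anchors_co_clustered": anchor_mod.contains_anchors,
        "excluded_clusters": summary.excluded_clusters,
        "response_summary": class_summary,
        "top_enriched_set": enrichment.index[0] if len(enrichment) else None,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return report


def simulate_to_dir(config: SimConfig, outdir: str | Path) -> PipelineConfig:
    """Generate the full synthetic study and write it as pipeline inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = simulate_study(config)
    io.write_expression_tsv(study["tissue_a"], outdir / "tissue_a.tsv")
    io.write_expression_tsv(study["tissue_b"], outdir / "tissue_b.tsv")
    io.write_expression_tsv(study["profile"], outdir / "profile.tsv")
    io.write_single_cell(study["single_cell"], outdir)
    io.write_expression_tsv(study["response"], outdir / "response.tsv")
    io.write_gmt(study["gene_sets"], outdir / "gene_sets.gmt")
    for name, truth in study["truth"].items():
        io.write_truth(truth, outdir / f"truth_{name}.tsv")
    return PipelineConfig(
        tissue_a=str(outdir / "tissue_a.tsv"),
        tissue_b=str(outdir / "tissue_b.tsv"),
        profile=str(outdir / "profile.tsv"),
        sc_mtx=str(outdir / "counts.mtx"),
        sc_genes=str(outdir / "genes.tsv"),
        sc_cells=str(outdir / "cells.tsv"),
        response_table=str(outdir / "response.tsv"),
        gmt=str(outdir / "gene_sets.gmt"),
        outdir=str(outdir / "results"),
        anchors=study["anchors"],
        seed=config.seed,
    )


def run_all(sim_config: SimConfig, outdir: str | Path) -> pd.DataFrame:
    """Simulate the study into ``outdir`` and run the pipeline on it."""
    pipe_config = simulate_to_dir(sim_config, outdir)
    return run_pipeline(pipe_config)
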