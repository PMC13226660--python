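"""File formats: expression TSV, MatrixMarket single-cell trio, GMT gene sets.

All tabular outputs are TSV with the gene id as first column; floats are
written with 6 significant digits to keep outputs diff-stable across runs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path,
                         index_label: str = "gene_id") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label,
                  float_format=FLOAT_FORMAT)


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene ids {dupes[:5]}")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values not allowed")
    return df


def write_single_cell(dataset: ad.AnnData, outdir: str | Path,
                      prefix: str = "counts") -> None:
    """Write counts as <prefix>.mtx (genes x cells) + genes.tsv + cells.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    x = dataset.X
    mat = sparse.csr_matrix(x) if not sparse.issparse(x) else x.tocsr()
    spio.mmwrite(str(outdir / f"{prefix}.mtx"), mat.T.astype(np.int64))
    pd.Series(dataset.var_names, name="gene_id").to_csv(
        outdir / "genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"cell_id": dataset.obs_names, "cluster": dataset.obs["cluster"].astype(str)}
    ).to_csv(outdir / "cells.tsv", sep="\t", index=False)


def read_single_cell(mtx: str | Path, genes: str | Path,
                     cells: str | Path) -> ad.AnnData:
    """Read a MatrixMarket genes x cells trio into a cells x genes AnnData."""
    mat = sparse.csr_matrix(spio.mmread(str(mtx)).T)
    gene_ids = pd.read_csv(genes, sep="\t")["gene_id"].astype(str)
    meta = pd.read_csv(cells, sep="\t")
    if "cluster" not in meta.columns:
        raise ValueError(f"{cells}: missing required 'cluster' column")
    if mat.shape != (len(meta), len(gene_ids)):
        raise ValueError(
            f"shape mismatch: matrix {mat.shape}, {len(meta)} cells, "
            f"{len(gene_ids)} genes"
        )
    return ad.AnnData(
        X=mat,
        obs=pd.DataFrame({"cluster": pd.Categorical(meta["cluster"])},
                         index=pd.Index(meta["cell_id"].astype(str),
                                        name="cell_id")),
        var=pd.DataFrame(index=pd.Index(gene_ids, name="gene_id")),
    )


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets: one set per line, ``name<TAB>description<TAB>genes...``.

    Blank lines are tolerated; a line with fewer than two fields raises
    with its line number. An empty file yields an empty collection with a
    warning.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line (need name, "
                    f"description, members)"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = [g for g in fields[2:] if g]
    if not sets:
        logger.warning("%s: no gene sets found", path)
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def write_truth(truth, path: str | Path) -> None:
    truth.to_frame().to_csv(path, sep="\t")


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
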