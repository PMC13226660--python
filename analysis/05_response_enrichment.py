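"""Fasting/refeeding response classification: per-genotype log2 fold
changes, the >2-fold responsive gate, blunted/enhanced calls at a >2-fold
genotype difference, and hypergeometric enrichment of gene sets among the
blunted genes with Benjamini-Hochberg adjustment.

Reads results/synthetic/, writes results/response/.
"""

import argparse
import json
from pathlib import Path

from secscreen import io
from secscreen.response import (
    classify_table,
    condition_means,
    enrich_gene_sets,
    summarize_classes,
)


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--indir", type=Path, default=Path("results/synthetic"))
    parser.add_argument("--outdir", type=Path, default=Path("results/response"))
    args = parser.parse_args()

    table = io.read_expression_tsv(args.indir / "response.tsv")
    classification = classify_table(condition_means(table))
    summary = summarize_classes(classification)
    universe = set(table.index[(table > 0).any(axis=1)])
    blunted = set(classification.index[classification["status"] == "blunted"])
    gene_sets = io.read_gmt(args.indir / "gene_sets.gmt")
    gene_sets.pop("hepatocyte_signature", None)  # single-cell signature
    enrichment = enrich_gene_sets(blunted & universe, gene_sets, universe)

    args.outdir.mkdir(parents=True, exist_ok=True)
    io.write_expression_tsv(classification, args.outdir / "classification.tsv")
    enrichment.to_csv(args.outdir / "enrichment.tsv", sep="\t",
                      float_format=io.FLOAT_FORMAT)
    with open(args.outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    frac = summary["blunted_fraction"]
    print(f"{summary['n_responsive']} responsive genes (>2-fold in control); "
          f"{summary['n_altered']} altered in the knockout")
    if frac is not None:
        print(f"blunted fraction of altered: {frac:.1%} "
              f"({summary['counts']['blunted']} blunted, "
              f"{summary['counts']['enhanced']} enhanced, "
              f"{summary['n_reversed']} reversed)")
    top = enrichment.iloc[0]
    print(f"top enriched set among blunted genes: {enrichment.index[0]} "
          f"(k={top['k']}/{top['K']}, p_adj={top['p_adjusted']:.2e})")


if __name__ == "__main__":
    main()
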