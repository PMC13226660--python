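# secscreen

Tools for nominating tissue-restricted secretory-pathway genes from
expression data, and for asking how their loss reshapes the liver's
fasting/refeeding transcriptional program. The pipeline mirrors the
computational trail that singled out *SEC16B* as a liver/intestine-specific
COPII gene tied to lipoprotein export: anchor-gene co-expression screening,
tissue-distribution correlation clustering, single-cell signature scoring,
and a genotype-dependent response classifier with over-representation
testing. Every stage runs on a built-in synthetic study with planted ground
truth, so the whole analysis is reproducible and testable without any
external download.

Intended users: computational biologists who want either the individual
stage functions (a thresholded co-expression screen, an AUCell-style
recovery-curve score, a fold-change-of-fold-change classifier) or the
end-to-end evidence join.

## Methods at a glance

**Anchor co-expression screen.** For anchor genes *a* ∈ {APOB, MTTP} and
tissues *t* ∈ {liver, intestine}, every gene *g* gets a Pearson correlation
r(g, a; t) on log2(x+1) expression. Candidates satisfy r > 0.6 in **all
four** (anchor, tissue) pairs — the intersection of four thresholded sets —
and are ranked by their minimum r.

**Tissue-distribution clustering.** Gene × tissue consensus profiles are
min-max scaled per gene to [0,1], correlated pairwise (Pearson), and
clustered agglomeratively on d = 1 − r with average linkage; the tree is cut
to a fixed module count and the module containing the anchors is the
tissue-restricted module of interest. Proportional normalization
(x_i / Σ_j x_j) supports the tissue-share heatmap view.

**Single-cell signature score.** Within each cell, genes are ranked by
count; for a gene set S and window T = ⌈0.05·G⌉ ranks, the score is
Σ_{x=1..T} hits(x) normalized by Σ_{x=1..T} min(x, |S|) — a recovery-curve
AUC in [0,1]. Per-cluster summaries report the percentage of expressing
cells and min-max-normalized mean expression, excluding clusters with fewer
than 10 cells.

**Response classifier.** Per gene and genotype, L = log2((refed + 1)/(fast
+ 1)) over replicate means. Genes with |L_CTL| > 1 are responsive; with
delta = sign(L_CTL)·L_KO − |L_CTL|, a gene is *blunted* if delta < −1,
*enhanced* if delta > 1, else concordant. Gene-set over-representation
among blunted genes uses the exact hypergeometric tail P(X ≥ k) with
Benjamini–Hochberg adjustment.

## Worked example

Run the numbered analysis scripts in order (they share `results/`):

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_screen.py
python analysis/03_tissue_modules.py
python analysis/04_celltype_scores.py
python analysis/05_response_enrichment.py
```

which prints (seed 1):

```
anchors ['g00000', 'g00001']; 35 candidates at r > 0.6
planted-module recall 92.1%; false candidates 0

8 modules over 160 non-constant genes
anchor module 1: 48 genes, anchors co-clustered=True
Jaccard with planted liver/intestine-restricted set: 0.83

excluded clusters (n < 10): {'neutrophils': 9}
signature AUC by cluster: endothelial=0.001, hepatocytes=0.295, ...
40 restricted genes flagged; F1 vs planted 1.00

200 responsive genes (>2-fold in control); 198 altered in the knockout
blunted fraction of altered: 84.8% (168 blunted, 30 enhanced, 60 reversed)
top enriched set among blunted genes: lipid_biosynthesis (k=32/40, p_adj=4.55e-28)
```

Reading: of the 40-gene co-expression module planted in both tissues, the
r > 0.6 four-way screen recovers 35/38 non-anchor members with no false
positives; the anchor-containing tissue module overlaps the planted
liver/intestine-restricted genes at Jaccard 0.83; the hepatocyte signature
scores highest in the hepatocyte cluster while the 9-cell cluster is
excluded; and among genes whose refeeding response is altered in the
knockout, ~85% are blunted, with the planted lipid-biosynthesis set the top
enrichment — the synthetic analogue of a feedback suppression of
lipogenesis.

The same run is available as one command, producing a joined per-gene
candidate report (screen × tissue module × cell-type restriction) with a
provenance block:

```bash
secscreen run-all --outdir results/run --seed 1
```

Individual stages are exposed as `secscreen simulate | screen |
cluster-tissues | celltype-score | classify-response`.

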