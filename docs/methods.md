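# Methods

This note documents the models behind `secscreen`: what each analysis
stage computes, what the synthetic-data generators emulate, the defaults
and why, and the numerical conventions. Nothing here states a result that
the test-suite or `scripts/acceptance.py` does not itself compute.

## Anchor co-expression screen

Correlations are sample Pearson coefficients computed per tissue between
each gene and each anchor gene. Expression is log2(x+1)-transformed by
default before correlating: TPM-like bulk values are heavy-tailed and the
log scale is the conventional robust choice; the raw scale remains
available (`transform="identity"`) and both paths are tested. The
candidate rule is strict (`r > threshold`, default 0.6) in every
(anchor, tissue) pair, with the anchors themselves excluded — their
self-correlation is vacuous. Genes constant across samples have no defined
correlation; they are reported as missing with a logged count rather than
silently assigned r = 0, which would corrupt the Venn region counts. When
tissues disagree on the gene universe the screen runs on the intersection
(logged). Candidates are ranked by minimum r across the four pairs,
ties broken lexicographically by gene id; the ranking is checked against a
brute-force sort. A threshold of −1 is accepted as the degenerate
lower bound (every non-constant, non-anchor gene passes).

## Tissue-distribution clustering

Each gene row of the consensus profile is min-max scaled,
(x − min)/(max − min); constant rows are mapped to zero and excluded from
correlation with a logged list. Pairwise gene correlation uses Pearson on
the scaled rows. Clustering is agglomerative on the distance d = 1 − r with
**average linkage**: the correlation-matrix semantics of the heatmap view
make (1 − r, average) the natural pairing, and the choice is configurable
(`--linkage`). The tree is cut by module count (default 8) rather than by
height, since a module count is the only granularity that is meaningful to
report across datasets; module ids are renumbered by first-gene occurrence
so output is deterministic. The anchor module is the cluster containing
both anchors; if they split, the majority module is returned with a flag
and a warning, ties going to the lower module id. Proportional
normalization divides each row by its sum (error on all-zero rows, naming
the gene).

## Single-cell signature score

The activity of a gene set in a cell is a recovery-curve AUC over the
cell's count-ranked gene list (the approach popularised by AUCell). Genes
are ranked by descending count with ties broken by ascending gene index —
a fixed, deterministic policy (a randomized-tie mode is out of scope).
With T = ⌈top_fraction · G⌉ and hits(x) the number of set members among
the top x ranks,

    score = Σ_{x=1..T} hits(x) / Σ_{x=1..T} min(x, |S|).

The denominator is the maximal attainable area, so scores are comparable
across set sizes and lie in [0,1]; an empty set scores 0. `top_fraction`
defaults to 0.05, the cited tool's convention. Counts are ranked raw:
within-cell ranking is invariant to per-cell scaling, so no normalization
is applied first. The implementation is tested for exact equality against
a direct enumeration oracle.

Cluster summaries report, per gene and cluster: the percentage of cells
with count > 0; the mean count min-max-normalized across included
clusters; and the relative percentage (the cluster's share of all
expressing cells). Clusters with fewer than `min_cells = 10` cells are
excluded from every statistic and reported — small clusters make
percent-expressing estimates unstable. A gene is called
cluster-restricted when its top cluster holds ≥ 90% of the proportionally
normalized mean expression and every other cluster has ≤ 10% of cells
expressing it; both thresholds are configurable and operationalise
"exclusive expression with negligible levels elsewhere".

## Response classifier

Replicate means per genotype × condition feed
L_g = log2((mean_refed + c)/(mean_fast + c)) with pseudocount c = 1 on
FPKM-scale means: FPKM reaches zero and the pseudocount keeps fold changes
finite; c is configurable. Classification is purely geometric, on the mean
fold changes — no per-replicate test statistic is computed at this stage
(dispersion modelling belongs to dedicated DE tools and is out of scope):

* responsive: |L_CTL| > 1 (log2; the twofold gate), strict;
* with direction = sign(L_CTL), p = direction · L_KO and
  delta = p − |L_CTL|: blunted if delta < −1, enhanced if delta > 1,
  else concordant (the twofold-difference diagonals);
* a knockout response in the opposite direction (p < 0) is flagged
  `reversed` rather than given a fifth status — under this geometry it is
  always also blunted, and the flag preserves the information without
  breaking the blunted/enhanced dichotomy.

The classifier is symmetric under jointly negating both fold changes, and
shrinking |L_KO| toward zero can only move calls toward blunted — both are
property-tested.

Enrichment of a gene set within a selection uses the exact hypergeometric
tail P(X ≥ k), computed by integer-arithmetic summation of the tail terms
(cross-checked against `scipy.stats.hypergeom` and, for small universes,
against explicit enumeration of all draws). The universe is the set of
genes expressed in at least one sample, not all annotated genes — an
unexpressed gene cannot be selected, and including it would inflate
significance. Benjamini–Hochberg adjustment is the standard step-up
procedure, cross-checked against `statsmodels`.

## Synthetic-data generators

The generators define the study conditions; they are deterministic given
the configuration seed (independent, fixed RNG streams per generator).

**Bulk co-expression** uses a one-factor Gaussian latent model per tissue:
module genes follow x = b + λ·f_s + σ·ε with a shared per-sample factor
f_s, giving the closed-form within-module correlation
r = λ²/(λ² + σ²) that the tests verify by Monte Carlo. Defaults λ = 0.9,
σ = 0.5 give r ≈ 0.76 — a strongly co-expressed module of the kind the
screen targets, comfortably above the 0.6 threshold at n = 60 samples.
The both-tissue module (40 genes, anchors first) loads in both tissues on
tissue-specific factors; a second 40-gene module loads in tissue A only;
the remaining genes are independent noise with matched marginal variance.
The baseline b = 10 keeps values ≳10 s.d. above zero, so the non-negativity
clip is inactive in practice and perturbs no correlation; it also makes the
log2(x+1) transform locally near-linear, so the factor-model correlation
survives the default transform. Module gene placement is contiguous at the
start of the id universe — transparent for debugging and irrelevant to any
statistic.

**Tissue profiles** plant the module genes as restricted to the designated
liver/intestine pair (high mean, near-zero elsewhere; off-target leakage
scales with the noise s.d., so the noise-free limit is exact), two decoy
groups restricted to other disjoint tissue pairs (giving a 3-block
structure for module-recovery tests; recorded under `module_label`), and
broadly expressed genes with a gene-specific level. Relative noise
defaults to 5%, typical of consensus-profile reproducibility.

**Single-cell counts** are negative binomial with variance μ + μ²/φ and a
single dispersion φ = 2 shared across genes — one knob with testable
moments, in the range typical of droplet data. Restricted genes have mean
5 in the hepatocyte cluster and 0.05 elsewhere; broad genes mean 2
everywhere; background mean 0.2. Cluster sizes default to
[120, 80, 60, 40, 9]; exactly one cluster is required to be smaller than
10 cells so the exclusion filter is always exercised.

**Response data** plant |L_CTL| ~ U[1.5, 3.5] for responsive genes (margin
above the twofold gate), with the knockout response shifted along the
control direction by Δ ~ U[1.2, 3] in log2 for blunted (subtracted — the
shift may overshoot zero, producing flagged reversals) and enhanced
(added) genes; defaults 85% blunted / 15% enhanced of 200 responsive genes
in a 2,000–5,000 gene universe. Replicate values are mean-one log-normal
perturbations (σ = 0.15, n = 4 replicates per genotype × condition) of
means constructed so the pseudocount-1 fold change of the noise-free means
equals the planted value exactly (the fasting mean is floored at
2^{−min L}·U[5, 50] to keep refed means positive). The emitted GMT
contains one set composed 80% of planted-blunted genes (the
lipid-biosynthesis analogue) plus four decoy sets drawn from null genes,
and the 11-gene hepatocyte signature used for single-cell scoring.

**What the generators do not emulate**: library-size and composition
artefacts, batch effects, doublets, gene-length effects, correlated noise
between genes outside planted modules, and read-level data. Passing
recovery tests therefore demonstrates correctness of the statistical
machinery under the stated models, not robustness to real-data artefacts
such as normalization bias or ambient contamination.

## Problem sizes and determinism

The test-suite exercises the full nominal study (2,000 genes × 60 samples;
5,000-gene response universe across 10 seeds) in a few seconds; smaller
fixtures are used where the planted structure, not scale, is under test.
All tabular outputs are written with 6 significant digits, and an
end-to-end run with a fixed configuration is byte-identical across
repetitions (verified in the tests); the pipeline's provenance block
records the package version, a hash of the analysis parameters (paths
excluded) and the seed.

## Known limitations

* The screen's candidate count depends on the correlation scale
  (log vs raw); both are exposed, and conclusions should be checked under
  both on real data.
* Average linkage on 1 − r is one defensible choice among several; module
  boundaries from a maxclust cut can be unstable for weakly separated
  blocks.
* The response classifier uses no replicate-level inference; genes near
  the fold-change thresholds flip class under noise, and the blunted
  fraction — a ratio of two noisy counts — is the stable summary.
* Heatmap/dot-plot rendering is deliberately out of scope; outputs are
  dot-plot-ready TSVs.
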