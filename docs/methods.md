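# Methods

## Problem and data model

The package asks whether bulk tumour transcriptomes, once non-cancer
tissue-of-origin expression is subtracted, group tumours by shared biology
across anatomical primary sites. Inputs are a gene × sample expression
matrix in the Xena/Toil dialect (log2(TPM+1)), a phenotype sheet giving each
sample's condition (tumour/normal) and primary site, a gene-biotype table,
and pathway gene sets in GMT format.

All analysis happens on the TPM+1 scale (`v → 2^v` on ingest). This is a
deliberate numerical choice: with numerator and denominator both ≥ 1, every
tumour/normal ratio is in (0, ∞) and every natural-log ratio is finite, so
the corrections below need no pseudo-count or masking logic.

## Cohort restriction

Only genes positively annotated `protein_coding` are kept; genes missing
from the annotation count as non-coding. Primary sites are retained only
when both the tumour and the normal side have at least `min_samples`
(default 20) samples — below that, the per-site mean normal profile is too
noisy to serve as a denominator. Sites whose tumour and normal histology is
not comparable cannot be fixed algorithmically; they are excluded through an
explicit config list (default: blood).

## Normalization

Two corrections, both natural-log ratios of tumour TPM+1 to a normal
reference:

* **Tissue-corrected**: reference is the arithmetic mean normal TPM+1 of
  the same gene at the tumour's own site
  (`Ĝ^tissue_il = (1/m_l) Σ_k Y_ikl`, `m_l` = normal count at site *l*).
  Removes site-of-origin expression exactly, at the risk of over-correction
  (each site gets its own reference).
* **Grand-mean-corrected**: reference is the **unweighted mean over sites
  of the per-site means**, `Ĝ^grand_i = (1/t) Σ_l Ĝ^tissue_il`. This is
  not the pooled mean over all normal samples — sites with many normals get
  no extra weight — so the reference is site-balanced and identical tumour
  profiles receive identical corrected values regardless of site.

With a single site the two corrections coincide (tested to 1e-12). The
site-partitioned three-dimensional views of the data are never materialized;
per-sample denominators are looked up through the sample sheet, which is
equivalent to multiplying by the binary site-classification matrices and
cheaper.

One consequence of an arithmetic-mean reference of log-normal data worth
knowing: the log of an averaged log-normal exceeds the average log by about
σ²/2, so corrected values centre slightly below zero even with no tumour
signal. This offset is shared by all samples and sites and therefore cancels
in every comparison the pipeline makes; the generator tests assert
exchangeability (tumour-side vs normal-side corrected means) rather than a
literal zero centre.

## Module detection

Unsigned weighted co-expression analysis re-implemented from the standard
formulas: Pearson correlation, adjacency `a_ij = |cor|^β` (signed variant
`((1+cor)/2)^β` available), topological overlap

    TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

average-linkage clustering of `1 − TOM`, static cut at height 0.99,
branches smaller than 30 genes left unassigned, modules labelled
`module-1, module-2, …` by decreasing size (deterministic given input).

The soft power β is the smallest candidate (1–20) whose connectivity
distribution fits a decaying power law with signed R² ≥ 0.85 **and** whose
mean connectivity stays ≥ 1 (`min_mean_connectivity`). The connectivity
floor is essential: at high powers an almost-empty network (mean k ≪ 1)
produces a spuriously excellent straight-line fit on the log-log histogram
while carrying no usable topology, and a module cut on its TOM collapses.
When no power qualifies, the fallback (6, the field's customary unsigned
default for large cohorts) is used and flagged. The fit itself uses 10
equal-width connectivity bins, regressing log10(frequency) on log10(mean
connectivity), R² negated when the slope is positive.

A static cut was chosen over the dynamic-hybrid tree cut: it is simpler,
deterministic, and sufficient for planted-module recovery; this is a known
divergence from the reference R implementation's default. Module expression
is the arithmetic mean of member-gene values (not an eigengene), on TPM+1
for the uncorrected branch and on the ln-ratio scale for corrected branches.

## Tumour clustering

Tumours are compared by cosine distance over the expression of **all
module-member genes** (not the module means, which are used for statistics
and display). On log-ratio values the cosine distance may exceed 1 (range
[0, 2]); vectors are not re-standardized since cosine is already
per-sample scale-invariant. Agglomeration is Ward in the D2 convention
(squared-distance Lance–Williams update, verified against a naive
recomputation). k is chosen in 2..min(20, n−1) by maximal mean silhouette
width computed from the same precomputed distances, ties toward smaller k.

## Enrichment and statistics

* **ORA**: upper-tail hypergeometric P(X ≥ k) for the overlap of each
  module with each pathway, universe = all protein-coding genes of the
  analysis, pathway members intersected with the universe first;
  Benjamini–Hochberg correction applied per module across pathways
  (family = one gene list's tests), significance at adjusted p ≤ 0.05.
* **Across clusters**: tie-corrected Kruskal–Wallis per module; the
  degenerate all-tied case returns H = 0, p = 1 (the tie-correction
  denominator vanishes and the limit is "no evidence"). Dunn's pairwise
  rank z tests follow, BH-adjusted across the C(g,2) pairs (the adjustment
  is configurable; the underlying publication does not state one).
* **Across sites**: Tukey–Kramer HSD (requires ≥ 2 observations per group
  and positive pooled variance).
* **Stratification**: per (site, cluster), upper-tail hypergeometric
  p with N = clustered tumours, K = site size, n = cluster size, k =
  overlap; a site is stratified when ≥ 2 clusters have p ≤ 0.05. The
  one-sided test is conservative under the null (measured rejection ≈ 3%
  at nominal 5%).

## Synthetic cohorts

The generator produces matched tumour/normal cohorts with known structure,
on the natural-log scale, then exponentiates and floors at 1 (TPM+1):

    normal:  baseline_g + site_offset_gs + ε
    tumour:  baseline_g + site_offset_gs + shift_m(cluster) + a_g f_mj + Σ b_gf u_fj + ε

with `ε ~ N(0, 0.5)`, per-gene baselines U(1, 6) (≈ 3–400 TPM), per-site
offsets N(0, 0.3), and per-(module, sample) latent factors `f`. The loading
`a_g` is scaled so two member genes correlate at the configured level within
a cluster (`a_g = σ √(ρ_g/(1−ρ_g))`), with per-gene ρ_g spread ±0.25 around
the target 0.6 — the hub/periphery connectivity spread real modules show.
Three weak transcriptome-wide factors `u` (variance share ≤ 0.3 split among
them) give the background the soft correlation floor of real data; without
them the connectivity distribution is degenerate and the scale-free power
sweep meaningless.

Defaults: 4 sites × 30 tumours + 25 normals, 1000 background genes, three
modules of 60/45/35 genes, three latent clusters with one module activated
per cluster at 2.0 ln units (≈ 7.4-fold — a strongly switched program,
e.g. immune infiltration). Activation must comfortably exceed the
within-cluster module-activity spread implied by ρ (σ·√(ρ/(1−ρ)) ≈ 0.61)
for clusters to be separable at all; 2.0 provides that margin while modules
stay detectable. Two sites are *stratified* (tumours split evenly across
latent clusters 1 and 2); the others fall wholly into the remaining
cluster(s), reproducing the stratified/unstratified dichotomy the
stratification statistic must detect.

What the generator does **not** emulate: tumour purity and microenvironment
mixtures, isoform structure, count-level noise (values are log-normal, not
negative binomial), gene–gene correlation beyond the factor structure, and
outlier samples. Passing recovery tests therefore show the pipeline is
correct and well-calibrated under its own model assumptions, not that real
cohorts will stratify.

## Problem sizes and determinism

Recovery checks use 20 independent cohorts of ~1140 genes × 120 tumours —
large enough for stable correlation estimates, small enough that the whole
suite runs on one CPU in minutes. Everything downstream of the generator is
deterministic: fixed seed and config give byte-identical matrices, module
labels, cluster assignments and manifests (config hash + per-stage counts
recorded per run).

## Known limitations

* The static tree cut cannot split nested modules the dynamic cut would.
* The scale-free fit on a 10-bin histogram is noisy below ~500 genes; the
  connectivity floor mitigates but does not remove this.
* Full TOM computation is dense O(n²) memory / O(n³) time; beyond ~20k
  genes a block-wise decomposition (out of scope) would be needed.
* Dunn's adjustment default (BH) and the k-search upper bound (20) are
  conventions, not derived quantities; both are configurable.
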