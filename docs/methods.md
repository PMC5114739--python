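# Methods

## Model and assumptions

The package treats bulk tumor expression as an additive mixture of cell
populations and asks only a *rank* question of the data: are the marker
genes of a cell population overexpressed in this sample relative to the
rest of the transcriptome?  Because the answer is computed per sample from
ranks alone, it is invariant to any strictly increasing per-sample
transform of the expression values, and hence portable across RSEM-style
RNA-Seq quantifications and microarray intensities without renormalization.
The score is a *relative* infiltration level: it supports comparisons of
one cell type across samples, not absolute cell counts, and scores from
different scoring calls are not directly comparable (the optional global
max − min normalization is per call).

### ssGSEA

For a sample with p genes, gene ranks are ascending 1..p with average ranks
for ties.  The enrichment score of a gene set with m members present in the
matrix walks all genes in decreasing-rank order and sums, at every
position, the weighted in-set ECDF (weights rank^α) minus the unweighted
out-of-set ECDF.  The engine evaluates the telescoped closed form of this
running sum in O(m) per (signature, sample) after one O(p log p) sort per
sample; the test suite proves the identity against a direct running-sum
oracle on every instance with p ≤ 8, m ≤ 3, and against an independent
external implementation (gseapy) to 1e-9 on random matrices.

Numerical/edge policies:

* α ≥ 0, default 0.25; α = 0 reduces the in-set ECDF to the unweighted
  step function.
* Ties in the walk carry identical average ranks; the order among tied
  genes is fixed by lexicographic gene id, so scores are deterministic.
* Set genes absent from the matrix are dropped with a warning, subject to
  `min_genes_present` (default 1); an empty intersection and a set that
  covers the whole matrix (out-of-set ECDF undefined) are errors.
* Negative expression values are accepted — ranks are well defined and the
  noise model below can produce them.

### Aggregate indices

Signature rows are standardized to mean 0, sd 1 across samples (sample sd,
n − 1 denominator; the choice only rescales, never reorders).  TIS is the
mean of the nine T-cell subset rows (CD8 T, T helper, T, central/effector
memory, Th1, Th2, Th17, Treg); IIS additionally averages macrophages, the
DC subsets, B cells, cytotoxic cells, eosinophils, mast cells, neutrophils
and the NK subsets.  The gamma-delta and follicular-helper T signatures
are excluded from both aggregates because several of their genes are
expressed in healthy brain tissue.  A `reduction="sum"` switch is exposed;
mean is the default since sum and mean differ by a constant factor and are
rank-identical.  APM is deliberately *not* an aggregate: it is the raw
ssGSEA score of the seven-gene MHC class I signature.  Log-ratios are
score differences (scores behave like log abundances); the median split
assigns ≤ median to the low group.

### Signature data

`data/bindea24.gmt` and `data/angiogenesis.gmt` are curated
reconstructions of the 24 immune-cell-type marker lists of Bindea et al.
(Immunity, 2013) and the 40-gene vascular/angiogenesis program of Masiero
et al. (Cancer Cell, 2013); the original supplementary tables are not
redistributable here.  The reconstructions preserve every structural
property the analysis depends on: 24 signatures totalling 509 distinct
genes, 501 of which occur in exactly one signature; sizes 33/35/37/24 for
the macrophage, NK, CD8 T and T-helper signatures used in the mixture
experiment (pairwise gene-disjoint); single-gene Treg (FOXP3) and pDC
(IL3RA) sets; and a 40-gene angiogenesis list.  Individual symbols may
deviate from the original supplements; downstream code never depends on
specific symbols beyond the APM and checkpoint genes, which are defined in
the text.  The files' sha256 digests are pinned in `data/MANIFEST.json`
and verified on load.  Gene matching is exact, case-sensitive symbol
equality — probe-to-gene collapsing and alias resolution are upstream
concerns.

## Synthetic data generators

The generators produce every input the pipeline consumes, at the study's
own scale where one is stated.  What they emulate — and what they do not —
bounds what a passing test shows: they reproduce the mixture *structure*
the analysis assumes (linear pooling, scaled noise, planted classes), not
RNA-Seq count dispersion, 450K probe chemistry, or correlated co-infiltration
of real tumors.

* **Mixing proportions** use the uniform-spacings construction (k − 1
  sorted U(0,1) draws → k gaps), i.e. flat Dirichlet; rows sum to one to
  1e-12 and coordinates are marginally Beta(1, k − 1).
* **Reference profiles**: one log-normal baseline per gene (meanlog 3,
  sdlog 1, the scale of normalized RNA-Seq) shared by all five cell types;
  each immune type multiplies its own signature genes by `fold`
  (default 5); the CD45⁻ profile overexpresses nothing.  The default
  universe is 20,032 genes containing the full signature panel plus
  synthetic filler genes.
* **Mixtures**: clean value = Σ_c π_c · ref_c(gene); at noise level S:1,
  independent Gaussian noise with sd = clean/S per (gene, sample), not
  clipped at zero (ranks are robust; beta values, by contrast, are
  proportions and are clipped).  The default sweep grid is
  {10, 9, ..., 1, 0.5}:1, covering both reported "extremely noisy"
  endpoints.
* **Clustered cohorts** plant three classes on a log2 scale: class 1
  raises the T-cell/APM/checkpoint genes by `effect`; class 2 raises
  angiogenesis genes by `effect` and the immune genes by a per-sample
  u·effect with u ~ U(0.25, 0.75) — sample-varying, intermediate
  infiltration, which keeps the class identifiable while remaining
  heterogeneous (full-range u would make its extremes indistinguishable
  from the other two classes by construction); class 3 is baseline.
  Log-normal per-entry noise (sdlog 0.35) supplies within-class spread.
* **Methylation cohorts** draw leukocyte/cancer probe levels with a
  bimodal separation (40% informative probes, separation 0.4–0.8 beta
  units, half leukocyte-high and half leukocyte-low) and mix them as
  tumor = f·B + (1 − f)·C + N(0, noise_sd), clipped to [0, 1]; the
  leukocyte reference emulates six healthy-donor profiles.

All generators take a `numpy.random.Generator`; a fixed seed reproduces
outputs bit for bit.

## Mixture-recovery validation

Per cell type, recovery is the Spearman correlation between the true
proportion column and the ssGSEA score row (the CD45⁻ compartment has no
signature and no correlation).  Significance uses an empirical null:
random signatures of exactly the real signature's size (33/35/37/24 genes
for macrophage/NK/CD8 T/T helper) drawn uniformly without replacement from
the gene universe and scored on the *same* mixture; p is the plain
fraction of null correlations ≥ the observed one, so p = 0 is reportable
(a smoothed (r + 1)/(n + 1) variant is opt-in).  The sweep draws fresh
proportions at every noise level, seed-controlled.  The full protocol is
1000 draws over an 11-level grid; the acceptance script and test suite run
a 200-draw null over the 9:1–4:1 range, which bounds the Monte Carlo error
of a p-value at ~0.07 worst-case (3/√200) — ample against observed nulls
centered at 0 with sd ≈ 0.1 and observed correlations near 0.98.

## Methylation leukocyte fractions

Anchors: B_k = mean beta over leukocyte reference samples; T_k = min
(leukocyte-high probes) or max (leukocyte-low probes) over tumor samples —
the theoretically purest tumor.  Probes with B_k = T_k have undefined
fractions and are dropped with a warning; ranking ties are broken by probe
id.  Per-probe fractions outside [0, 1] are retained (they shape the
density and are reported as a diagnostic share), but the KDE mode search
is restricted to [0, 1] with step 0.001, Silverman bandwidth; zero-variance
inputs bypass the KDE.  Two estimator properties matter in practice:
first, the anchor assumption — the cohort must contain a near-pure tumor,
otherwise all estimates shrink toward zero by about f_min; second, at
cohort sizes of a handful of samples the sample that *is* the per-probe
minimum acquires a spurious density spike at exactly zero.  Both vanish at
realistic cohort sizes; the recovery tests therefore use cohorts of 40
tumors (10 per planted fraction), where estimates land within ±0.03 of
truth at noise sd 0.05.

## Cohort clustering

The 28-feature panel (24 immune cell types, angiogenesis, PD-1, PD-L1,
CTLA-4) is scored jointly and clustered as-is — raw ssGSEA scores, no
per-feature re-standardization (a `standardize_features` flag exists).
Linkage is Ward on Euclidean distances in the Ward.D2 sense (Lance-
Williams update on squared distances, scipy's `ward`), cut by `maxclust`.
Semantic labels for k = 3 are a declared convention: clusters ranked by
mean T-cell subset score, highest → T cell enriched, lowest →
non-infiltrated; ties broken by mean checkpoint-target score, then by
cluster id, so labeling is deterministic; a constant panel triggers a
warning.  `predict_nearest_centroid` is a plain Euclidean nearest-centroid
convenience for transferring labels to new cohorts — it is not a trained
classifier.

## Problem sizes

The test suite and acceptance script run the mixture experiment at its
full stated scale (20,032 genes, 200 samples per level, six noise levels)
with a 200-draw null; smaller universes (2,000–5,000 genes) appear only in
unit tests of mechanics, where the property under test is scale-free.
Clustering tests use 80-sample cohorts over ~4,000 genes; methylation
tests use 4,000–10,000 probes.

## Known limitations

* Signature files are reconstructions (above); symbol-level fidelity to
  the original supplements is not guaranteed.
* ssGSEA scores are relative within one scoring call; cross-cohort
  comparability requires joint scoring.
* The leukocyte-fraction estimator inherits the purest-sample anchor
  assumption and degrades on very small cohorts.
* Generators do not model count overdispersion, platform batch effects,
  or biologically correlated infiltration of distinct cell types; survival
  modeling, differential expression and classifier transfer between real
  cohorts are out of scope.
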