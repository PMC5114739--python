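# immunedecomp

Gene-expression decomposition of the tumor immune microenvironment.

Bulk tumor RNA is a mixture of cancer cells, stroma and immune infiltrates.
`immunedecomp` estimates the relative infiltration levels of 24 immune cell
populations directly from a gene-by-sample expression matrix using
single-sample gene set enrichment analysis (ssGSEA) — a rank-based
overexpression score that needs no reference expression vectors and works
on both RNA-Seq and microarray data.  It is aimed at computational
oncologists who want per-sample immune profiles, aggregate infiltration
indices, and the simulation machinery to validate rank-based decomposition
end to end.

## What it computes

**ssGSEA.** Within each sample, genes get ascending ranks 1..p (ties →
average rank).  Walking genes in decreasing-rank order, the enrichment
score of a gene set G (|G| = m) accumulates the difference between a
weighted in-set ECDF and the unweighted out-of-set ECDF:

    ES = Σ_{i=1..p} [ ECDF_in(i) − ECDF_out(i) ],
    ECDF_in(i)  = Σ_{g ∈ G, pos(g) ≤ i} rank(g)^α / Σ_{g ∈ G} rank(g)^α,
    ECDF_out(i) = #{g ∉ G, pos(g) ≤ i} / (p − m),

with α = 0.25 by default.  Scores are optionally normalized by the global
(max − min) of one scoring call.

**Aggregate indices.**  After row-standardizing the score matrix, the
T-cell infiltration score (TIS) is the mean over nine T-cell subset
signatures and the immune infiltration score (IIS) the mean over 22
adaptive + innate signatures; APM is the raw ssGSEA score of a seven-gene
MHC class I antigen-presentation signature.  Differences of two scores are
interpreted as log cell-count ratios (presets: CD8⁺T/Treg, Th17/Th2).

**Validation harness.**  Known-proportion in silico mixtures of five
reference profiles (four immune types + CD45⁻ non-immune) with S:1
Gaussian noise; recovery is the Spearman correlation between the true
proportions and the inferred scores, with bootstrap p-values from
size-matched random-signature nulls.

**Methylation leukocyte fractions.**  From beta values, the per-probe
fraction f_ik = (T_ik − T_k)/(B_k − T_k) over the 1000 most leukocyte-high
and 1000 most leukocyte-low probes, aggregated per sample as the mode of a
kernel density over [0, 1].

**Infiltration classes.**  Ward/Euclidean hierarchical clustering of a
28-feature panel (24 immune cell types + angiogenesis + PD-1/PD-L1/CTLA-4)
into three classes: T cell enriched, heterogeneously infiltrated,
non-infiltrated.

The 24 immune signatures (509 genes, 501 signature-unique) and the 40-gene
angiogenesis signature ship as checksummed GMT files; see
`docs/methods.md` for their provenance.

## Worked example

Validate the scoring on a synthetic mixture at a 4:1 signal-to-noise
ratio:

```python
import numpy as np
import immunedecomp as im

rng = np.random.default_rng(0)
refs = im.make_reference_profiles(p=20_032, fold=5.0, rng=rng)
props = im.simulate_mixing_proportions(200, k=5, rng=rng)
experiment = im.mix_and_add_noise(refs, props, snr=4, rng=rng)

rho = im.recovery_correlations(experiment)
print(rho.round(3))

null = im.random_signature_null(experiment, "CD8_T", 37, n_draws=200, rng=rng)
print("bootstrap p (CD8_T):", im.bootstrap_pvalue(float(rho["CD8_T"]), null))
```

Output:

```
macrophage    0.987
NK            0.983
CD8_T         0.989
CD4_T         0.980
Name: spearman_rho, dtype: float64
bootstrap p (CD8_T): 0.0
```

Each number is the Spearman correlation between the known mixing
proportion of that cell type across the 200 simulated samples and its
ssGSEA score — even at substantial noise, ranks recover the planted
infiltration levels almost perfectly, and none of 200 size-matched random
37-gene signatures correlates as strongly as the real CD8⁺ T signature
(bootstrap p = 0).

The same operations are available from the shell:

```bash
immunedecomp score --expr expr.tsv --out scores.tsv
immunedecomp aggregate --scores scores.tsv --out scores_with_tis_iis.tsv
immunedecomp validate-mixtures --seed 1 --draws 1000 --out sweep.tsv
immunedecomp cluster --expr expr.tsv --k 3 --out clusters.tsv
immunedecomp leukocyte-fraction --tumor betas.tsv --ref pbmc.tsv --out fractions.tsv
```

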