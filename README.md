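# stepweight

Weighted single-step genomic BLUP (WssGBLUP) for animal breeding at desk
scale: pedigree and genomic relationship algebra, animal-model BLUP,
six iterative SNP-weighting strategies, forward validation, and a
window-based single-step GWAS — together with a synthetic-herd
generator so the whole evaluation chain can be exercised and tested
without proprietary registry data.

## The problem

Genetic evaluation of livestock predicts each animal's additive genetic
merit (its breeding value) from phenotypes recorded on it and its
relatives. Pedigree-based BLUP (PBLUP) uses the numerator relationship
matrix **A**; single-step GBLUP (ssGBLUP) augments it with a genomic
relationship matrix **G** for the genotyped subset, combining all
information in one hybrid matrix **H**. When a trait is controlled by a
few large quantitative trait loci (QTL), giving every SNP the same
variance wastes information: weighted single-step GBLUP (WssGBLUP)
iteratively re-estimates per-SNP variances and rebuilds **G** with a
diagonal weight matrix **D**, either per SNP or per window of
consecutive SNPs.

## The model

Single-trait animal model on phenotypes adjusted for fixed effects:

    y_adj = 1 mu + Z a + e,   Var(a) = K sigma_a^2,  Var(e) = I sigma_e^2

with K = A (PBLUP) or K = H (ssGBLUP), solved through Henderson's
mixed-model equations. The genomic pieces:

* **G** = M D M' / (2 Σ p_i (1 − p_i)) — VanRaden's matrix on genotypes
  centered by twice the allele frequency, with SNP weights in D;
* **H**⁻¹ = **A**⁻¹ + [[0,0],[0, (0.95 G + 0.05 A22)⁻¹ − A22⁻¹]];
* back-solved SNP effects û = λ D M' G⁻¹ â with λ = 1/(2 Σ p_i(1−p_i)),
  where â are the direct genomic values DGV_i = −Σ_{j≠i} g^{ij} GEBV_j / g^{ii};
* weighting strategies on σ̂²_{u,i} = 2 p_i (1−p_i) û_i²: default
  (d_i = σ̂²_{u,i}), constant (σ̂²_{u,i} + c with c the iteration-1
  maximum), nonlinear-A (d_i = CT^{|û_i|/sd(û) − 2}, capped), and
  largest / mean / summed windows of 25–100 consecutive SNPs; weights
  are normalized to mean one and the loop repeats for 10 iterations;
* validation: predictive ability r = cor(y_adj, GEBV) in the youngest
  generation, accuracy r/√h², bias as the slope of y_adj on GEBV, RMSE;
* ssGWAS: percent of additive variance per 1 Mb window,
  var(Σ_{i∈window} M_i û_i) / σ²_a × 100.

## Worked example

```bash
stepweight simulate --scenario oligogenic --seed 1 --outdir herd/
stepweight run --config herd/config.yaml
```

The simulated herd has 2000 animals over 5 generations, 2000 SNPs on 5
chromosomes, a trait with 5 QTL carrying 80% of the additive variance
(h² = 0.35), and 40% of animals genotyped. The run prints the
per-iteration validation report (abridged):

```
  method strategy  iteration  n_val  predictive_ability  accuracy  bias_slope  rmse  is_best_iteration
   PBLUP        -          1    400               0.188     0.318       0.721 9.859              False
 ssGBLUP  default          1    400               0.279     0.471       0.883 9.621              False
WssGBLUP  default          2    400               0.328     0.554       0.585 9.738              False
WssGBLUP  default          3    400               0.352     0.595       0.523 9.904               True
WssGBLUP  default          4    400               0.350     0.592       0.510 9.964              False
...
```

Iteration 1 of the weighted method *is* ssGBLUP (unit weights); the
accuracy column is r/√h²; a bias slope of 1 means no dispersion bias.
Here genomic information lifts validation accuracy from 0.32 (PBLUP) to
0.47 (ssGBLUP), and SNP weighting adds more on this few-QTL trait
before degrading at later iterations. `stepweight gwas --config ...`
writes the per-window percent of genetic variance.

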