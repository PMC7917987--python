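# Methods

This note documents the statistical machinery in `stepweight`, the
choices made where the methodology is genuinely open, what the
synthetic herds do and do not emulate, and the problem sizes the test
suite and `scripts/acceptance.py` use.

## Relationship matrices

**A** is built by the tabular method on a topologically sorted
pedigree; unknown parents are unrelated, non-inbred founders (no
unknown-parent groups, no metafounders). Inbreeding coefficients come
from a Meuwissen–Luo style accumulation of `a(i,i) = Σ L²_ij D_j` over
each animal's ancestor closure, so F never requires dense A. **A**⁻¹
uses Henderson's rules with inbreeding-corrected Mendelian-sampling
variances `D_i = 0.5 − 0.25 (F_s + F_d)` (0.75 − 0.25 F with one known
parent, 1 with none); the sparse result matches dense inversion of the
tabular A to 1e-10 on every tested pedigree up to n = 500. A22 is taken
by subsetting dense A, adequate below a few thousand genotyped animals.

**G** is VanRaden's first matrix with a diagonal SNP-weight matrix D.
Allele frequencies are the observed frequencies of the genotyped set,
computed once after filtering and held fixed across weighting
iterations. The denominator `2 Σ p(1−p)` uses post-filter SNPs and
never includes the weights; weights enter only through D, and their
normalization to mean one keeps the denominator's interpretation
stable across iterations. Centering by observed frequencies puts the
ones vector in G's null space, so raw G is singular by construction;
the evaluation always uses the blend `Gb = 0.95 G + 0.05 A22`. The
blend coefficients are configurable (including the literal pair
0.095/0.05 that sometimes circulates, which shrinks G about sevenfold
and is almost certainly a misprint of 0.95/0.05 — the default here).
No tuning of G's scale to A22 is applied by default. H⁻¹ is assembled
sparsely as A⁻¹ plus the `Gb⁻¹ − A22⁻¹` block scattered over the
genotyped animals.

SNP filters: minor allele frequency < 0.01 and heterozygote-frequency
deviation from 2p(1−p) above 0.15 (both thresholds configurable in
[0, 0.5]); filtering precedes the frequency computation used in G.
Missing genotypes are rejected; a mean-imputation utility exists as a
preprocessing step only.

## Solving and adjustment

Mixed-model equations are solved by a dense Cholesky solve below 6000
equations and preconditioned conjugate gradients (tolerance 1e-10)
above. Fixed-effect identifiability uses a first-level-zero constraint
per factor, giving deterministic, order-stable solutions; rank
deficiency is reported with the confounded column names.

The adjustment model removes fixed effects (batch factors, optional
covariates) with a pedigree animal model on the full data; adjusted
phenotypes are `y − Xb̂`, identically EBV + residual. The multi-trait
model stacks traits with Var(u) = G0 ⊗ A and Var(e) = R0 ⊗ I; animals
missing some traits have the residual covariance sub-blocked to their
observed traits. The pipeline's single simulated trait uses the
single-trait adjustment; the multi-trait solver exists for the general
contract and is verified against a dense GLS oracle.

Yearling weight standardization:
`YW = ((W_t − W_{t−1})/(t − t_{−1}))·(365 − t_{−1}) + W_{t−1}` (kg).

EM-REML (single trait) iterates Henderson's EM updates
`σ²_a ← (â'A⁻¹â + tr(A⁻¹C_aa)σ²_e)/q`, `σ²_e ← y'ê/(n − r(X))` to a
relative change of 1e-6 (max 500 rounds, warning on non-convergence).
Fixed effects are absorbed and a one-time generalized
eigendecomposition of (Z'SZ, A⁻¹) makes each round O(q²); REML
likelihood is non-decreasing across rounds. It exists for
parameter-recovery checks on synthetic data; multi-trait AI-REML is
out of scope and variance components are normally configuration inputs.

## Weighting loop

Iteration 1 always solves with unit weights and therefore *is*
unweighted ssGBLUP, for every strategy. Each iteration back-solves SNP
effects from the direct genomic values (not the GEBVs) of all
genotyped animals — DGVs strip the parent-average part that reflects
pedigree rather than genomic information — using the current D and the
blended G-inverse. Strategy specifics:

* constant: c is the maximum per-SNP variance of iteration 1,
  pre-normalization, frozen thereafter;
* nonlinear-A: sd(û) is the sample standard deviation over all SNPs of
  the current iteration; the cap (5 or 20) binds the weight itself;
* windows: consecutive, non-overlapping, never spanning chromosome
  boundaries (configurable); the last window per chromosome may be
  short; window statistics use pre-normalization variances.

Raw weights are floored at 1e-8 of their mean (so û = 0 SNPs keep a
positive, negligible weight and D stays invertible) and rescaled to
mean one, once per iteration, after any strategy-specific offset. The
loop never stops early: the full 10-iteration trace is recorded and
the accuracy-maximizing iteration is marked post hoc, mirroring how
such analyses select the reporting iteration.

## Validation and ssGWAS

Forward validation splits phenotyped animals at a birth-year cutoff;
validation phenotypes are masked in the evaluation model but their
adjusted phenotypes (from the full-data adjustment fit) serve as the
response for metrics. Predictive ability is Pearson correlation; the
accuracy denominator √h² comes from the pedigree-based single-trait
variance components supplied in configuration; bias is the slope of a
simple linear regression (with intercept) of adjusted phenotype on
prediction; RMSE is in trait units. Zero-variance predictions yield
NaN metrics rather than an error.

The ssGWAS decomposes `var(Σ_{i∈window} M_i û_i)/σ²_a × 100` over 1 Mb
windows (half-open, anchored at 0 per chromosome) or k-SNP blocks,
using the single-trait solve's back-solved effects.

## Synthetic herds

The generator emulates the data structure the evaluation consumes:
discrete generations (400 founders + 4 × 400 offspring by default),
a small sire pool (25/generation), gene dropping from founder
haplotypes with Bernoulli(p) alleles at p ~ U(0.05, 0.95) and Haldane
recombination at 1 cM/Mb, traits with a QTL layer (effects scaled so
each QTL contributes a set fraction of σ²_a; QTL are drawn among
common SNPs with MAF ≥ 0.1 so they are observable panel variants) plus
a pedigree-transmitted polygenic remainder, generation-structured
batch effects (SD 5 on a trait with phenotypic variance 100), partial
phenotyping, and genotyping restricted to the youngest generation plus
a random fill from the two preceding ones (40% overall).

Presets: *oligogenic* — 5 QTL carrying 80% of σ²_a (a carcass-weight-
like architecture); *polygenic* — 500 equal QTL carrying all of it (a
marbling-like architecture); both h² = 0.35, 2000 SNPs on five 100 Mb
chromosomes, 50% of pre-validation animals phenotyped, the last
generation validated.

Not emulated: realistic LD from long-term drift/selection (founder
haplotypes are in linkage equilibrium; LD arises only from the five
simulated generations), selection, mutation, genotyping error, multiple
correlated traits in the pipeline, and the real data's scale (tens of
thousands of animals and ~44k SNPs). Passing tests therefore
demonstrate the algebra and the qualitative behavior of weighting
(genomic > pedigree accuracy; window weighting helps oligogenic traits
and is neutral for polygenic ones; over-iteration degrades accuracy) —
not the magnitudes any particular cattle population would show.

## Problem sizes and numerical choices

The test suite and acceptance script run ten seeded replicates of each
preset (2000 animals), five EM-REML recoveries at n = 2000, and ten
single-QTL (30% of σ²_a) GWAS replicates at the preset scale with the
weighted model run for 3 iterations — sizes chosen so the whole chain
stays at desk scale while each comparison has enough replication to be
directional. Symmetry is enforced to 1e-12 where matrices are
symmetrized; PSD checks tolerate −1e-8 eigenvalue noise; identity
checks in tests use the tolerances stated alongside them. Degenerate
inputs (all SNPs filtered, singular blends, zero-variance predictions,
sd(û) = 0) raise informative errors or warnings rather than
propagating NaNs.

## Known limitations

Dense A and A22 cap practical pedigrees at ~10⁴ animals; no APY or
other large-scale G⁻¹ approximations; no maternal/permanent-
environment/random-regression models; no binary PLINK or VCF input;
single-trait evaluation only in the pipeline. The window-vs-single
comparison in this synthetic setting tends to favor single-SNP
weighting because simulated QTL are isolated variants estimated with
little noise, whereas field analyses at chip density usually report
window weighting ahead; both routes are implemented and compared by
the acceptance script.
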