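# Methods

## The model

Expression of gene *j* measured for individual *i* in context *c* (a tissue in
bulk RNA-seq, a cell type in single-cell data) is modeled as

    E_c = g β + g γ_c + ε_c,

where **g** are the individual's cis-genotype dosages, **β** are cis-genetic
effects shared by every context, **γ_c** are context-specific effects, and the
noise vector (ε_1, …, ε_C) of one individual is correlated across contexts
(shared environment, technical batch, cellular composition).  The goal is a
per-context genetic predictor of expression that *separates* the shared and
specific parts: the specific predictor should carry essentially no shared
signal, so that downstream context fine-mapping and context-specific TWAS are
not confounded by pleiotropy.

## Decomposition

After residualizing each gene-context on its covariates and standardizing to
mean 0, population variance 1, the observed value splits exactly into a
between-individual and a within-individual part:

    E_ijc = Ē_ij·  +  (E_ijc − Ē_ij·),

with Ē_ij· the mean over individual *i*'s **observed** contexts.  The first
term is the context-shared component (one value per individual), the second
the context-specific deviation.  The identities the package enforces exactly:
reconstruction at every observed entry, per-individual zero sums of the
deviations, and (with complete data) global orthogonality of the two
components.  Individuals observed in a single context carry a zero deviation
but still contribute to the shared component, so the shared model's sample
size is maximal.  Taking means over observed contexts only is unbiased under
missingness that is unrelated to expression, which is how the generator
creates it.

A grouped variant inserts a group-shared level (e.g. a brain-shared component
across brain tissues): group mean minus global mean, with deviations taken
from the group mean.  Singleton groups are collapsed, since their group-shared
term would coincide with the deviation.

An equivalent view of the decomposition is a random-intercept linear mixed
model: as the number of individuals grows, the shared component converges to
the individual-level BLUP up to shrinkage.

## Predictors

For each gene an elastic net (mixing parameter 0.5, the convention of the
TWAS weight-training lineage; penalty from an inner cross-validated path) is
fit to the shared component and to each context's deviation.  Genotypes are
standardized inside each training split and exported weights are returned on
the dosage scale.  Two cross-validation layouts exist:

* **nested** (default, `outer_cv=10`, `inner_cv=10`): outer folds give honest
  out-of-fold predictions, inner folds select the penalty on the outer
  training split only.  Use this whenever the out-of-fold R² or LRT p-values
  are the product of interest (eGene discovery, hierarchical FDR).
* **selection-only** (`outer_cv=None`): one inner CV selects the penalty on
  all data; out-of-fold predictions are produced at that penalty.  Roughly
  2.5× cheaper; the optimism is confined to the penalty choice.  Used by the
  large simulation studies, where accuracy is measured against the simulated
  truth in an independent cohort and the optimism cannot leak into the
  reported numbers.

Out-of-fold predictions are centered within each held-out fold before any
scoring.  Without this, the fold models' intercepts (training means) leak the
held-out fold's mean with a negative sign, which inflates the squared
correlation under the null by roughly (number of folds)/n and makes the LRT
anticonservative — at n = 60 with 5 folds the null rejection rate at the 0.05
level was ~45% before the correction and ~5–10% after.

The per-context **full** model regresses the observed expression of context
*c* on the two out-of-fold component predictions (OLS with intercept).  The
fitted weights re-sign the specific deviation where needed and shrink a
noise-only component toward zero; the exported per-SNP weight vector is the
same linear combination of the refit component weights,
w_sh·β̂ + w_sp·γ̂_c, so each gene-context receives a single weight vector.
A component whose prediction is constant is dropped and the full model
degenerates to a single predictor.

Significance is a Gaussian likelihood-ratio test against the intercept-only
null: statistic n·log(RSS₀/RSS₁), χ² with 1 df for component models and 2 df
for the full model.  The χ² null is asymptotic; the calibration tests use
n ≥ 400.  Model selection per gene-context takes the model with the greatest
cross-validated adjusted R² against the observed expression, ties preferring
fewer predictors.  Adjusted R² is 1 − (1 − R²)(n − 1)/(n − p − 1) with R² the
squared Pearson correlation (defined as 0 for a constant prediction).

## Comparators

*Context-by-context*: an independent cross-validated elastic net per context
on the observed (non-decomposed) expression — the classic single-tissue TWAS
recipe, sharing all CV machinery with the component models.

*Joint group LASSO*: minimizes Σ_c RSS_c/(2 n_c) + λ Σ_m ‖B_m·‖₂, so each
SNP's coefficients across contexts are jointly zero or nonzero.  This is the
published joint-training objective reimplemented, not a wrapper of the
original package; the 1/(2 n_c) weights balance unequal context sample sizes
and individuals missing from a context simply drop from its loss term.  The
solver is block-coordinate descent on per-context standardized columns (unit
curvature makes the block update an exact group soft-threshold) with an
active-set strategy and BLAS KKT screening; convergence at max coefficient
change < 1e-6, capped at 10⁴ sweeps (a non-converged fit returns the best
iterate, flagged).  The penalty comes from 5-fold CV over a geometric path of
8 values down to 0.05·λ_max; the selected ratio sits well inside that range
in all our studies.

## Hierarchical FDR

Hypotheses form a gene → context → model/method tree.  Internal nodes use
Simes aggregation (valid under the positive dependence typical of tests that
share genotypes); selection is top-down Benjamini–Hochberg with the
multiplicative level adjustment: level q at genes, q·(R₁/G) within a selected
gene's contexts, and q·(R₁/G)·(R₂,g/C_g) at a selected gene-context's leaves.
Rejection sets are tree-consistent by construction, and leaves from several
methods can be pooled into one tree (duplicate leaf keys are an error).
Under a global null the gene-level false discovery proportion is controlled
at q (checked empirically in the calibration suite).

## Synthetic data

The generator reproduces the study conditions the predictors were designed
for:

| parameter | default | meaning |
|---|---|---|
| contexts C | 20 | GTEx-like multi-tissue design |
| cis-SNPs M | 500 | independent loci, MAF ~ Unif[0.05, 0.50], dosage Bin(2, MAF) |
| sample sizes | 75–410 | per-context, uniform, sampled from a common pool of 410 |
| h²_shared / h²_specific | 0.3 / 0.1 | variance shares of expression |
| causal probability π | 0.05 | Bernoulli mask for shared eQTLs |
| truly-specific rate λ | 1 | Poisson count of specific eQTLs off the shared-causal set |
| fraction of contexts with specific effects | 0.5 | which contexts carry specific heritability |
| noise correlation ρ | 0 (swept 0–0.6) | equicorrelated intra-individual noise |

Specific effects sit on the shared-causal SNPs (subsampled at rate min(1, λ);
at the default λ = 1 that is all of them), with the Poisson(λ) truly specific
eQTLs placed on SNPs without a shared effect and drawn from the same
N(0, h²_c/(λMπ)) law — no separate scale is defined for them.  Per-context
noise variance is 1 − h²_shared − h²_specific(c) with a single equicorrelation
ρ.  Effect sizes are rescaled per gene so each component's realized genetic
variance equals its target heritability: on unstandardized dosages the raw
N(0, h²/(Mπ)) law realizes only ≈ 0.37·h² of variance (the 2p(1−p) dosage
variance), which would contradict the stated heritabilities and break the
law-of-total-variance bookkeeping (Var(E) ≈ 1).  The literal unrescaled law
remains available (`rescale_realized_h2=False`).

Missingness: each context's sample is drawn uniformly from the pool without
replacement; in the (measure-zero at these sizes) event an individual is
observed nowhere, they are swapped into a random context for an individual
observed elsewhere, so sample sizes stay in range and everyone is observed at
least once.

Phenotypes: a configured number of causal genes (default 100) contribute a
configured number of contexts each (default 3); each selected pair's true
genetic expression is standardized and receives an effect
δ ~ N(0, σ²_ge/n_pairs).  Noise variance is 1 − σ²_ge so total phenotypic
variance is ≈ 1 with genetic share σ²_ge (default 0.2).  A literal
1 − σ²_ge/n_pairs noise variance — which would leave the phenotype's genetic
share at σ²_ge/n_pairs — is available behind `literal_noise_variance` for
comparison.  For the TWAS architecture sweep, each gene's shared proportion
of total expression heritability is drawn Unif(0, 1), every context is
eligible for specific effects, and the phenotype generator re-selects causal
pairs each replicate while the trained weights are reused (many phenotypes
over one expression panel).

What the generator does **not** emulate: LD between cis-SNPs (loci are
independent), rare variants, trans effects, non-Gaussian expression noise,
and covariate structure (covariates enter the pipeline as given).  Passing
tests therefore demonstrate the statistical machinery under the assumed
generative model, not robustness to LD-confounded weights or count noise in
real RNA-seq.

## TWAS evaluation

Imputation into an external cohort is the dosage-weight product; association
is the individual-level simple regression t-statistic of the phenotype on the
standardized imputation, reported as Z (|Z| capped at 40 — inert for the
rank-based AUC) with a two-sided normal p.  This is the individual-level
equivalent of the summary-statistic association a TWAS pipeline reports for a
single predictor.  A gene's discovery score is the maximum |Z| over its
contexts (and models, when several are pooled); genes with no forwarded model
(nominal LRT p ≥ 0.1, the weight-forwarding rule) score 0.  Power is the
area under the ROC over causal versus non-causal genes, computed by the
Mann–Whitney identity.

## Problem sizes in the shipped studies

The acceptance script runs the full study design at reduced gene counts,
chosen so the whole script completes on a single CPU in well under half an
hour: 10 genes per noise-correlation setting (ρ ∈ {0, 0.3, 0.6}) for the
prediction study, with accuracy measured against the true genetic components
in an independent 410-individual cohort; and for the TWAS power study 80
genes (40 causal × 3 contexts), two total-heritability settings {0.1, 0.4},
100 phenotype replicates per setting over an external cohort of 10,000.  The
simulation studies use the selection-only CV layout with a 12-value penalty
path and 5-fold inner CV; spot checks against the 10-fold/20-value
configuration moved the reported quantities by less than their Monte-Carlo
error.  The test suite exercises the same checks at miniature scale.

## Known limitations

* The LRT and the CV-R² scoring assume Gaussian residuals; heavy-tailed
  expression should be transformed upstream.
* The selection-only CV layout's p-values inherit mild optimism from the
  shared penalty choice; use the nested layout for discovery claims.
* The specific-component predictor targets the *deviation* γ_c − γ̄, not γ_c
  itself; with many contexts the difference is small, but with few contexts
  the deviation under-represents the specific effect.
* The group-LASSO comparator is a clean reimplementation of the published
  objective; results obtained with the original package's optimizer and
  defaults can differ.
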