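# Methods

This note describes the statistical machinery implemented in `prsup`:
what each component computes, the conventions it follows, and the
numerical choices that matter for reproducing its results.

## 1. Data model and quality control

Genotypes are held as an `n × m` dosage matrix (counts of the effect
allele, `NaN` for missing) with a variant table
(`id, chrom, pos, effect_allele, other_allele`) and per-sample
population labels. PLINK 1 binary files (`.bed/.bim/.fam`, SNP-major)
are read and written directly; the FAM family id carries the population
label.

`qc_filter` removes variants with minor-allele frequency below 0.01,
Hardy–Weinberg-equilibrium exact-test p-value below 1e-7, or missingness
above 5%, and keeps only the first of any duplicated variant id. The HWE
test is the exact conditional test: given the observed allele counts, the
p-value sums the probabilities of all heterozygote counts whose
probability does not exceed the observed one, evaluated with log-gamma
arithmetic.

`harmonize` aligns summary statistics to a reference panel on
(chromosome, position), flips the effect sign when the alleles are
swapped, and drops strand-ambiguous (A/T, C/G) or irreconcilable
variants. `merge_populations` intersects two cohorts' panels with the
same rules to support pooled analyses.

## 2. Simulation

*Genotypes.* Ancestral allele frequencies are drawn `p ~ U(0.05, 0.5)`.
Each population diversifies them under a Balding–Nichols model,
`p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F)`, parameterized by the fixation
index `F` (default 0.1); the Hudson estimator applied to two simulated
populations recovers `F` (verified in the tests). Haplotypes are sampled
by thresholding latent Gaussian AR(1) blocks (block length 20,
autocorrelation 0.9 by default), producing local LD that decays within a
block and vanishes across block boundaries; two haplotypes sum to the
diploid dosage.

*Phenotypes.* With `Z` the column-standardized dosages, exactly 10% of
variants (a fixed count, not an expectation) receive causal effects
`β ~ N(0, h²/M_causal)` and

```
y = Z β + e,   e ~ N(0, 1 − h²),
```

so `E[Var(Zβ)] = h²` and `E[Var(y)] = 1`. Multi-population phenotypes
share one causal architecture; each cohort standardizes its own
genotypes and draws its own residuals. The calibration is checked at
scale by `scripts/acceptance.py` (mean variance ratio 0.5 ± 0.02, mean
total variance 1 ± 0.03 over 50 replicates).

## 3. Marginal GWAS

Per-variant ordinary least squares of the phenotype on the (by default
standardized) dosage with an intercept, vectorized across variants:
`β̂_j = S_xy/S_xx`, `SE` from the residual sum of squares with `n − 2`
degrees of freedom, two-sided t-test p-values. Optional covariates are
projected out of both phenotype and genotypes first, with the degrees of
freedom reduced accordingly. Monomorphic variants get the sentinel
`(β̂, SE, p) = (0, ∞, 1)`. The meta-population GWAS is exactly: merge the
two cohorts' panels and samples, then run the same marginal scan on the
pooled matrix.

## 4. LD estimation

LD is estimated from a reference panel as Pearson correlations of
standardized dosages within a physical window (1 Mb by default), giving
a banded matrix per chromosome. Two copies are kept:

* the **raw band**, used for clumping r² queries;
* the **solver matrix** `(1−λ)R + λI` (ridge λ = 0.05), used by the
  closed-form and Gibbs adjusters.

Hard band truncation can make the solver matrix indefinite, which breaks
the joint precision `N·R + I/σ²` the samplers rely on. The solver copy
is therefore repaired by eigenvalue clipping (floor `max(λ, 1e-4)`)
followed by a diagonal renormalization back to unit diagonal; this
preserves positive definiteness, leaves an identity matrix unchanged,
and alters well-conditioned bands only marginally.

## 5. Effect-size adjustment

All methods take harmonized summary statistics plus the LD object and
return per-variant adjusted effects on the standardized-genotype scale.

**Clumping + thresholding (`pt`).** Greedy clumping by ascending
p-value: a variant is kept iff its r² with every kept variant within
250 kb is below 0.1 (ties in p break by chromosome, then position).
Each p-value threshold in a 14-point grid (1e-8 … 1) then zeroes
non-surviving effects; the threshold is tuned downstream.

**Double weight (`dw`).** Each effect is resampled `β* ~ N(β̂, SE²)` over
Monte-Carlo draws; `π̂_j` is the fraction of draws in which `|β*_j|`
ranks in the top Z (default 100), and the adjusted effect is `π̂_j β̂_j`.
With SE → 0 this degenerates to a top-Z indicator; with Z = m it returns
the marginal effects.

**Infinitesimal model (`ldpred_inf`).** The closed form
`(D + (M/(N h²)) I)⁻¹ β̂`, solved per chromosome on the solver matrix
`D`. With identity LD every effect shrinks by exactly
`1/(1 + M/(N h²))` — `1/3` at `M = N = 1000, h² = 0.5` — which the
acceptance suite asserts to machine precision.

**Point-normal Gibbs (`ldpred`).** Prior
`β_j ~ π N(0, h²/(πM)) + (1−π) δ₀`, one chain per π in an 11-point grid.
Single-site updates use the residualized marginal effect
`r_j = β̂_j − (R_j·b − R_jj b_j)` with likelihood variance `1/N`;
inclusion follows the exact posterior odds and included effects are
drawn from `N(N r_j/(N + 1/σ²), 1/(N + 1/σ²))`. The reported estimate is
Rao-Blackwellized: the post-burn-in average of (inclusion probability ×
conditional mean). At π = 1 the chain reproduces the infinitesimal
closed form (within 2% relative RMS on a 200-variant panel in the
acceptance suite); on a two-variant panel it matches the exact
enumeration posterior.

**Finite mixture (`mixture`).** Prior
`β_j ~ Σ_c π_c N(0, γ_c σ²_β)` with `γ = (0, 0.01, 0.1, 1)` for
summary-level LD (the individual-level grid `(0, 1e-4, 1e-3, 1e-2)` is
provided for dense LD computed from training genotypes). Component
memberships are sampled from exact conditional probabilities, `π` from a
`Dirichlet(1 + counts)` update, and `σ²_β` from a scaled inverse
chi-square update (ν₀ = 4); both hyper-parameter updates can be frozen,
in which case equal non-null scales reduce the sampler to the
point-normal model exactly.

**MAF-dependent prior (`sbayes_s`).** The two-component special case of
the mixture whose non-null variance is scaled per variant by
`[2p_j(1−p_j)]^S`. `S < 0` encodes negative selection (rarer variants
carry larger effects). At `S = 0` the output is bit-identical to the
plain point-normal mixture at the same seed. Optionally `S` is sampled
by random-walk Metropolis (step 0.1) under an `N(0, σ²_s)` prior; on
data generated with `S = −0.5` the posterior mean recovers the sign.

**Scoring.** `score` matches effects to the target panel on
(chromosome, position), sign-flips swapped alleles, drops ambiguous or
unresolvable variants, and returns `Z w` on the target's standardized
dosages. Scoring is linear in the effects, so combining at the effect
level and at the score level are interchangeable.

## 6. Predictor combination

Given per-population predictors, NNLS (Lawson–Hanson) solves

```
min_w ||y − Σ_j w_j PRS_j||²   s.t.   w ≥ 0
```

on validation data, after centering y and the PRS columns and
standardizing columns for conditioning (weights are mapped back to the
raw-PRS scale). Constant PRS columns receive weight 0 with a warning.
`combine_effects` forms the per-variant weighted sum over the union
panel, harmonizing allele orientation to the first predictor carrying
each variant.

## 7. Evaluation protocol

Cohorts are split 7 : 1.5 : 1.5 into training/test/validation by
largest-remainder apportionment, stratified by population and shuffled
by seed. Accuracy is the squared Pearson correlation between PRS and
phenotype (constant predictors score 0). Hyper-parameters are chosen by
validation-set argmax, ties breaking toward the smaller value.
Sample-id disjointness between the training split and both evaluation
splits is asserted at every stage boundary.

*Meta-population design.* Per phenotype replication and target
population: GWAS and LD are computed on the pooled training split
(target alone, and target pooled pairwise with each other population),
hyper-parameters are tuned on the target's test split and the final R²
is reported on its validation split. This tune-on-test /
report-on-validation order follows the benchmarked protocol verbatim;
since both splits are disjoint from training and from each other, the
roles of the two held-out splits are symmetric.

*Multiple-population design.* Per seeded re-split (20 by default) of the
target cohort: the target's own summary statistics and LD come from that
fold's training split; auxiliary populations contribute fixed external
summary statistics harmonized to the target panel. Method
hyper-parameters and the NNLS weights are fit on the validation split,
and R² is reported on the test split. Summaries report per-recipe mean
and SD across folds plus accuracy relative to a baseline set of recipes.

All samplers, splits and benchmark drivers are deterministic given their
seeds; repeated runs produce byte-identical performance tables.
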