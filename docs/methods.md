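# Methods

## Model and scope

The package analyses a continuous trait (body surface area, m²) in a
four-group multi-ethnic cohort with a single mixed linear model containing
every genetic term of interest simultaneously: per-locus additive (a) and
dominance (d) effects, digenic epistasis (aa, ad, da, dd) for locus pairs,
and — as random effects — the ethnic-group means (e) and the group-specific
deviation of every genetic term (ae, de, aae, ade, dae, dde). Sex enters as
a fixed block effect; a conditional model adds one lifestyle cofactor
(walk, exercise, read, smoke, transportation) as a fixed covariate, so the
genetic effects it reports are those net of that cofactor.

Genotypes are coded xA = 1/0/−1 for QQ/Qq/qq and xD = 1 for Qq, 0
otherwise; epistasis codes are elementwise products of the marginals, and
each interaction incidence column is the coding zeroed outside its ethnic
group. Mean-imputed fractional dosages map continuously
(xA = dosage − 1, xD = 1 − |dosage − 1|). The Q allele is the first-listed
allele of the input file; a flag can reorient to minor-allele-as-q.

## Quality control

SNPs with minor-allele frequency below 0.05 or call rate below 90% are
removed (a SNP failing both is tallied once, under MAF, so drop counts
conserve). Phenotype outliers are removed in two fixed stages: first the
quartile fence — values above Q2 + 1.5·IQR or below Q1 − 1.5·IQR, with
type-7 quantiles; the upper anchor is the *median* as the source procedure
prints it, with a `q3` switch for the conventional Tukey fence — then a
single pass of standardized-residual filtering (|ε − μ_ε|/σ_ε > 3) under
the fitted full model. A zero residual spread keeps all subjects with a
warning. Missing cofactor values drop a subject only from that cofactor's
conditional run.

## Testing: Method III reductions and permutation thresholds

All tests are built from reductions in sums of squares
R(S) = y′X_S(X_S′X_S)⁻X_S′y computed with a pivoted rank-revealing QR.
Variance components for the random groups are solved from the expected
values of the reduction differences along a fixed fitting order
(fixed → e → ae → de → aae → ade → dae → dde → residual); the expectation
coefficients are the trace quantities ‖Q_k′Z_g‖²_F differences, the
residual variance comes from the full-model SSE, and negative
method-of-moments estimates are kept signed internally and truncated at
zero only for heritability reporting. On a one-way random-groups layout
this reproduces the classical ANOVA method-of-moments estimator exactly
(unit-tested), and with an empty random part every F below reduces to the
OLS partial F (oracle-tested to 1e−8).

The association F for a term set is [R(full) − R(full∖terms)]/df₁ divided
by the full-model residual mean square. The single-locus scan jointly tests
a, d and their eight group incidences; the pairwise scan jointly tests the
four epistasis codings plus sixteen incidences with both loci's marginal
structure in the background. Because the background basis and each unit's
orthonormalized block can be precomputed, a permuted phenotype costs one
matrix product; the permutation engine processes hundreds of permutations
per GEMM. Phenotypes are permuted within sex × ethnicity strata to preserve
the block and group composition of the null; the critical F is the
empirical (1 − α) quantile of the per-permutation maximum F, and
P_EW(f) = (1 + #{draws ≥ f})/(n_perm + 1) (add-one, so no zero p-values).
Defaults are 2,000 permutations and α = 0.05; desk-scale runs in the tests
and acceptance script use 200–500 permutations, at which the resolvable
−log10 P_EW floor is log10(n_perm + 1).

The exhaustive 2D scan over all pairs is infeasible at biobank scale, so the
pairwise stage is two-stage: loci passing a liberal pointwise threshold
(default p ≤ 1e−3, configurable; the synthetic analyses use 0.05 with a cap
of 30 so that epistasis-only loci, whose marginal leakage is weak, can reach
the pairwise stage) are paired exhaustively.

## Estimation: Gibbs sampling

The selected multi-locus model is refit by a two-block Gibbs sampler: the
full coefficient vector is drawn jointly from its Gaussian conditional
(flat priors on fixed effects, normal shrinkage on random effects), then
each random group's variance and the residual variance are drawn from
conjugate inverse-gamma conditionals. Defaults: 20,000 iterations, 4,000
burn-in, thin 1; estimates are posterior means and standard errors
posterior standard deviations; a split-chain potential-scale-reduction
above 1.1 on any coefficient flags non-convergence.

Two numerical choices matter here and are deliberate:

* **Identifiability.** Each fixed coding column equals the sum of its four
  group incidences exactly, so the a-versus-ae split (and likewise for
  every other term) is identified only through the shrinkage prior on the
  random side. A near-flat variance prior lets that direction wander and
  inflates posterior standard errors severalfold. The group-variance prior
  is therefore inverse-gamma(2, 0.005·var(y)): a small finite prior mean
  that pins the unidentified direction, while four coefficients of a real
  interaction easily dominate it in the conditional.
* **Shrinkage granularity.** Pooling one variance per interaction *type*
  across all loci (the Method III component structure) over-shrinks a
  single locus with a genuine group-specific effect toward the many null
  loci. The sampler therefore assigns one variance per interaction type per
  locus/pair by default (`variance_granularity="unit"`); `"type"` pooling
  is retained as an option.

## Heritability decomposition

V_P is defined as the model decomposition sum: the 12 genetic/G×E component
variances plus the residual variance (sex-block and ethnic-mean variance
excluded, matching the decomposition the component table is built from).
The default component-variance mode (`empirical`) is the across-subject
variance of each component's fitted contribution averaged over posterior
draws; the `alpha_formula` mode reproduces the printed per-effect rule
h²_g = α·σ²_g/V_P with α = 2, 1, 4, 2, 2, 1 for a, d, aa, ad/da, dd and
σ²_g the squared posterior-mean effect times its coding-column variance
over α (the α then cancels; the printed definition of σ²_g is ambiguous, so
both modes are labelled in output metadata). Draw-averaged empirical
variances include the posterior-uncertainty trace term and therefore read
slightly above the realized values when many terms are estimated; with the
priors above the bias is small (e.g. 23.6% estimated vs 22.5% realized
total heritability in the acceptance run at n = 5,000). The three printed
aggregates (h²_T, h²_D+, h²_GE) are always recomputed from components at
write time, never copied.

Per-effect experiment-wise significance in the effect tables is the unit's
joint-F P_EW gated by a pointwise |t| ≥ 2 filter; when coding collinearity
(a vs d at low MAF) pushes every |t| of a selected unit below 2, the
strongest effect retains the unit's significance. Referring each
coefficient's squared t to the max-joint-F permutation null was evaluated
and found far too conservative (a joint F over ~10 df dominates any single
squared t), which is why the unit-level attribution is used.

## Cofactor-impact classification

For every effect significant in the base or a conditional model (default
threshold −log10 P_EW > 5; desk-scale runs use the α-equivalent
−log10 0.05): significant in both with |Δestimate| ≤ 2 pooled SE → `×`
(not affected); both significant with a larger change → `+`/`−` by whether
|estimate| grew or shrank; significant only in the base model → `√`
(caused/contributed by the cofactor); significant only in the conditional
model → `√` (suppressed by the cofactor). The 2-pooled-SE rule makes the
+/− calls explicit where the source scheme gives no numeric rule.
Conditioning is implemented as the fixed covariate written in the model
equation, not as a two-step conditional-phenotype transformation.

## Synthetic cohorts

The generator emulates the study conditions: ethnic proportions
38/12/28/22% (E-A, C-A, A-A, H-A), sex Bernoulli(0.5), ancestral allele
frequencies uniform on [0.05, 0.5] with Balding–Nichols group divergence
(default F_ST = 0.05) and Hardy–Weinberg genotypes within group; columns
whose realized pooled MAF falls below 0.05 are redrawn so the panel mimics
post-QC data. Effects are specified as target shares of the phenotypic
variance and converted to coefficients through realized coding-column
variances, so realized heritability tracks the target (the `paper_scale`
scenario plants ~75% total heritability with dominance-related shares
dominating, as in the published decomposition; BSA-scale defaults
μ = 1.85 m², sex effect 0.1 m², V_P = 0.04). Cofactors follow one of three
rules — independent noise; mediator (SNP → cofactor → phenotype, so
conditioning shrinks the SNP effect); masker (a latent residual share
observed by the cofactor, so conditioning unmasks weak effects). The
scenario coefficients (e.g. masked direct share 5% of the pre-masker scale
against a 12× latent variance) were chosen so the three scenarios are
separated at n = 1,500 with 200 permutations.

Not emulated: linkage disequilibrium, relatedness, genotyping batch
effects, non-Gaussian residuals. Passing tests therefore demonstrate
correctness of the statistical machinery under the model's own assumptions,
not robustness to the LD structure or confounding of real cohort data.

## Problem sizes

The package defaults mirror the study settings (5,324 subjects, 2,000
permutations, 20,000 Gibbs iterations). The test suite and acceptance
script run the same code at desk scale as their own design choice:
calibration on 200 null cohorts of n = 500 × 200 SNPs with 500
permutations; recovery at n = 5,000 × 60 SNPs; scenario classification at
n = 1,500 × 30 SNPs over 50 seeds per scenario; Gibbs runs of 1,500–4,000
iterations where posterior means stabilize far earlier than the default.

## Known limitations

* The error stratum for every F-test is the full-model residual mean
  square; no Satterthwaite-style synthetic denominators are formed for
  random-term tests. The construction is documented so it can be swapped.
* The A/AE (and analogous) variance splits are prior-identified, as
  described above; component tables should be read with that in mind.
* P_EW for pairwise units is referred to the single-locus permutation null
  (one critical F for the experiment, as in the source analysis); pair
  statistics have more numerator degrees of freedom, making their P_EW
  mildly conservative in the tails.
* No REML/ML fitting, no kinship random effect (the model targets
  ethnicity structure, not cryptic relatedness), no higher-than-digenic
  epistasis.
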