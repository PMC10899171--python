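# Methods

## Scope and model

`famlipid` estimates how strongly dyslipidemia and serum lipid levels run
in families, using pedigree structure only (no genotypes). The chain of
analyses mirrors a longitudinal family cohort design: relatives are typed
from a pedigree, lipid phenotypes are classified per phase against ATP III
cut-points, familial resemblance is quantified by relative-pair
correlations and by the variance explained by the pedigree in a polygenic
mixed model.

The core model is the polygenic ("animal") model

    y = X b + g + e,   g ~ N(0, A sigma_g^2),   e ~ N(0, I sigma_e^2),

where A = 2 * Phi is the additive (numerator) relationship matrix built
from the kinship matrix Phi, and family heritability is
h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2). Because A comes from the
pedigree alone, h^2 absorbs every source of familial resemblance with the
same covariance pattern — notably shared household environment. The
synthetic-data generator plants a household component precisely so tests
can demonstrate that absorption (the estimator recovers genetic +
household share, not the genetic share alone).

For binary dyslipidemia the model is a probit liability threshold: an
unobserved liability z ~ N(eta, 1) with eta = mu + X b + g determines
status by sign, and liability-scale heritability is
sigma_g^2 / (sigma_g^2 + 1).

## Pedigree machinery

Kinship uses the standard recursion over a topological order
(phi_ij = mean of i's kinship with j's parents; phi_ii = (1 + F_i)/2 with
F_i the parental kinship). Founders are unrelated and non-inbred. Pair
typing classifies each within-family pair once under the precedence
first-degree > second-degree > spouse > cousin; spouse precedes cousin so
consanguineous marriages are reported as spouse pairs whose kinship column
exposes the blood relation — the consanguinity rate is exactly the
fraction of spouse pairs with kinship > 0. Spouses are inferred from
shared offspring, with an explicit spouse list covering childless couples.
Half-siblings share exactly one parent; avuncular excludes half-avuncular
unless enabled.

## Phenotype processing

- LDL-C defaults to Friedewald (TC - HDL - TG/5), undefined at
  TG >= 400 mg/dL; the function is a replaceable hook.
- Treated total cholesterol is divided by 0.8 to undo the average
  medication effect; by default this happens before LDL derivation.
- ATP III flags: TC >= 200, TG >= 200, LDL >= 160; HDL < 40 (men) /
  < 50 (women), all mg/dL; boundary semantics are tested exhaustively.
- Two per-person trait scenarios: FM (first phase at age >= 18) and AM
  (mean over non-missing eligible phases; per-trait n reported). AM
  averages away phase-level measurement error, which is why AM-based
  heritabilities exceed FM-based ones when such error exists — a
  directional property the test suite checks with 20 replicates.
- Before correlation/heritability, traits are residualized on age and sex
  (log scale for TG/HDL/LDL, raw for TC) and mapped to normal scores by
  the rank-based inverse normal transform with Blom offset 3/8 (midranks
  for ties). Residualize-then-transform is invariant to affine rescaling
  of age.

## Cohort rules

Dyslipidemia is longitudinal: drug history at any phase, or at least one
ATP III flag in at least two phases. An optional strict mode also requires
age > 40 for the drug basis — the source cohort definition is grammatically
ambiguous on this, and age alone cannot define disease. Point prevalence
at the baseline phase is necessarily cross-sectional (>= 1 flag at
baseline, or drug by baseline): the two-phase rule cannot fire at the
first observed phase. Periodic prevalence adds later incident cases (by
the longitudinal rule) over all ever-observed persons, each counted once.

Exclusions (each configurable): never reaching age 18; extreme lipids
(robust z > 5 on the log scale via median/MAD, or absolute bounds); a
simplified familial-hypercholesterolemia screen (TC > 290 or LDL > 190
plus a flagged first-degree relative — a deliberate stand-in for full
clinical criteria); drug use under age 40; drug use or CVD at 40+.

## Estimators

Likelihood fit. The Gaussian model is profiled to one dimension: with
A = U diag(lambda) U', the rotated model has independent residuals with
variances sigma_p^2 (h lambda_i + 1 - h), so beta and sigma_p^2 are
profiled out analytically and (RE)ML reduces to 1-D optimization of h on
[0, 1] (Brent, xatol 1e-8, endpoints checked; boundary estimates flagged
and reported without SE). Pedigree matrices are block-diagonal by family,
so the eigendecomposition is done per connected component — cohorts of
thousands stay sub-second. The SE of h^2 is the inverse curvature of the
profile log-likelihood (central differences). The ML loglik equals the
dense multivariate-normal density at the fitted parameters to 1e-8 on
small pedigrees (oracle test).

Gibbs sampler. Same rotation; full conditionals are normal for beta
(flat prior) and for the rotated genetic values (independent scalars),
and scaled-inverse-chi-square for both variances, prior df 5 and prior
scale half the response variance (for the probit model: half the variance
of the 0/1 response, <= 0.125, keeping the prior weak against the fixed
unit residual). Zero eigenvalues pin the corresponding genetic
coordinates to zero. The probit sampler augments a truncated-normal
latent liability per iteration (inverse-CDF sampling, clipped at +/-12).
Default desk schedule: 50,000 iterations, 25,000 burn-in, thinning 25,
2 chains; the production-scale 400,000/200,000/40 schedule is available
via config and retains exactly 5,000 samples per chain. Convergence is
monitored by the Gelman-Rubin PSRF sqrt(((n-1)/n W + B/n)/W); runs used
here sit near 1.000, against an acceptance bound of 1.03. Posterior h^2
is summarized as the mean of per-sample variance ratios, never the ratio
of posterior means.

Familial correlations. Exchangeable pair types (siblings of the same
composition, spouses, cousins, half-sibs) use the double-entry
product-moment estimator, which equals Fisher's one-way ANOVA intraclass
correlation in its population-mean-square form (SSB-SSW)/(SSB+SSW)
exactly; ordered types (parent-offspring by sex, grandparental,
avuncular) use the interclass Pearson correlation with the senior member
first. Confidence intervals come from a cluster bootstrap over families
(default 2,000 resamples, multinomial weights over per-family sufficient
statistics), because pairs within a family are dependent; Fisher-z
intervals would understate uncertainty. Binary statuses run through the
same machinery (phi-type correlation), validated against a numeric
bivariate-normal exceedance oracle under the liability model.

Family history. Offspring exposure is the count of affected parents among
parents of known status (unknown-status parents leave the denominator).
The odds ratio comes from an age- and sex-adjusted logistic regression
(maximum likelihood via statsmodels), reference category "no affected
parent", contrasts ">= 1 affected" (pooling both-affected) and "both
affected"; Wald 95% CIs; constant covariates (single-sex strata) are
dropped automatically; separation raises an error rather than returning
an unbounded estimate. Family clustering is ignored in the fit to match
the plain-logistic convention; the cluster bootstrap in the ICC module is
the pattern to borrow if robust CIs are needed.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults are the study
conditions the rest of the suite assumes.

- Pedigrees: nuclear families with configurable sibship distribution
  (default 2-4); optional second generation (children marry founders with
  probability 0.5); consanguinity as a Bernoulli mixture with a
  3-generation cousin-marriage template (2 consanguineous of 5 marriages),
  with the mixing weight solved so the expected fraction of consanguineous
  spouse pairs equals the target (feasible below 0.4; the default target
  used in tests is 0.28).
- Ages: generation-stacked (youngest analysis generation ~ N(28, 5),
  26 years per generation up), advancing exactly 3 years per phase over 5
  phases, matching the cohort cadence.
- Traits: sex-specific means/SDs default to the adult cohort values (TC
  194.43/45.6 male, 182.56/80.3 female, etc.); TG/HDL/LDL are log-normal
  by moment matching, TC normal with a 40 mg/dL floor (the wide female SD
  would otherwise produce negative concentrations). Variance decomposition
  on the modeling scale: additive genetic (default share 0.42, drawn as
  N(0, A sigma_g^2) through the per-family factorization of A), household
  (0.10, shared by the whole family), phase error (0.20, independent per
  phase), remainder as person-level permanent environment. A small linear
  age trend centred at 38 years is added and removed again by the
  adjustment step.
- Disease: liability = genetic + residual with variances (h^2, 1 - h^2),
  default h^2 = 0.41, threshold set for 40% prevalence.
- Drug (3%) and CVD (2%, age > 40) flags and 5% per-cell missingness are
  assigned at person level; all randomness flows from one seed through
  per-stage child seeds, so every artifact is reproducible byte for byte.

What the generator does not emulate: assortative mating, secular trends,
age-dependent variances, genotype data, and — importantly — the joint
distribution of the four lipids (they are simulated independently given
the shared family structure). One visible consequence: with the default
marginal distributions, the ATP III flags fire for most adults across 5
phases (a male HDL mean of 38.8 already sits below the 40 cut-point), so
the flag-based longitudinal prevalence is far higher than a real cohort's
and the flag-based status is nearly degenerate for logistic contrasts.
Pipeline stages that need a balanced binary outcome can therefore run on
the generator's liability-model status (`--status-source true`). Passing
tests demonstrate estimator correctness under the planted model, not
calibration of the flag prevalence to any real population.

## Problem sizes and numerical choices

Test and acceptance workloads are sized for a single CPU: recovery
studies use 200-500 families (about 1,000-2,500 individuals), 100
replicates for the Gaussian bias check (|bias| < 0.03 against planted
0.42), 3 replicate datasets for the probit check (posterior-mean average
within 0.07 of planted 0.41 — a single 400-family dataset has
realization SD ~ 0.05, so averaging tests recovery rather than one
dataset's luck), and 20 replicates for the FM/AM direction check
(>= 18/20 majority). Eigenvalues are clipped at zero below 1e-10; PSD is
enforced at -1e-8; ML boundary estimates are reported as 0/1 with a flag;
inverse-CDF truncated-normal draws clip the uniform at 1e-12.

## Known limitations

- No household/common-environment variance component in the estimators
  (deliberately: pedigree h^2 absorbs it, and the generator makes that
  visible); no dominance or epistasis; no marker-based relatedness.
- The probit sampler fixes the residual liability variance at 1 and is
  identified only up to that scale.
- The FH screen is a simplified threshold rule, not a clinical diagnosis.
- Logistic CIs ignore family clustering.
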