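# famlipid

Family-based dyslipidemia analysis for longitudinal cohort data: pedigree
kinship, relative-pair familial correlations, family-history odds ratios,
and polygenic heritability of lipid traits and dyslipidemia — plus a
synthetic cohort generator with known ground truth so every stage can be
validated without access to private cohort data.

## Who this is for

Genetic epidemiologists working with family cohorts where the phenotypes
are serum lipids (TC, TG, HDL-C, LDL-C) measured over repeated phases and
the relatedness information is a pedigree rather than genotypes. The
package reproduces the standard analysis chain of such studies end to end
and makes each step testable on simulated data.

## The model

Relatedness enters through the additive (numerator) relationship matrix
A = 2&Phi;, where &Phi; is the kinship matrix computed from the pedigree by
the standard recursion. Quantitative traits follow the polygenic mixed
("animal") model

```
y = Xb + g + e,   g ~ N(0, A sigma_g^2),   e ~ N(0, I sigma_e^2)
```

with family heritability h² = sigma_g² / (sigma_g² + sigma_e²) — a
pedigree-based quantity that absorbs shared-environment resemblance along
with additive genetics. Binary dyslipidemia uses a probit liability
threshold: liability z ~ N(mu + Xb + g, 1), affected when z > 0, with
liability-scale h² = sigma_g² / (sigma_g² + 1). Estimation is by
profile-likelihood (RE)ML and by a Gibbs sampler (latent-variable
augmentation for the probit case), with Gelman–Rubin convergence
diagnostics. Familial correlations use double-entry intraclass
correlations for exchangeable pairs (siblings, spouses) and interclass
correlations for ordered pairs (parent–offspring), with family-cluster
bootstrap confidence intervals. See `docs/methods.md` for details.

## Worked example

Simulate a 300-family cohort (sibships 2–4, ~1,500 individuals), plant a
trait with heritability 0.42, and estimate it both ways:

```python
import numpy as np
from famlipid import (SimulationConfig, simulate_pedigree,
                      simulate_breeding_values, kinship_matrix,
                      relationship_matrix, fit_polygenic_ml,
                      gibbs_gaussian, gelman_rubin, MCMCConfig)

cfg = SimulationConfig(n_families=300, sibship=(2, 4), seed=7)
ped = simulate_pedigree(cfg)
A = relationship_matrix(kinship_matrix(ped))

rng = np.random.default_rng(7)
g = simulate_breeding_values(A=A, sigma_g2=0.42, seed=rng)
y = g + rng.normal(0, np.sqrt(0.58), len(ped))

vc = fit_polygenic_ml(y, A=A)
print(f"REML  h2 = {vc.h2:.3f} (SE {vc.se_h2:.3f})")

res = gibbs_gaussian(y, A=A, cfg=MCMCConfig(n_iter=10_000, burn_in=4_000,
                                            thin=3, n_chains=2, seed=8))
h2 = res.samples("h2")
print(f"Gibbs h2 = {h2.mean():.3f} (sd {h2.std():.3f}), "
      f"PSRF(sigma_g2) = {gelman_rubin(res.per_chain('sigma_g2')):.3f}")
```

prints

```
REML  h2 = 0.417 (SE 0.046)
Gibbs h2 = 0.419 (sd 0.044), PSRF(sigma_g2) = 1.002
```

Both estimators recover the planted 0.42 within one standard error, and a
PSRF of 1.002 (well below the 1.03 convergence bound) says the two Gibbs
chains mixed.

The same analyses run as a pipeline from the shell:

```sh
famlipid all --config cohort.yaml --out run/ --seed 1
```

which writes, per stage: `pedigree.ped`, `phenotypes.tsv`, `kinship.tsv`,
`pairs.tsv`, typed-pair ICC tables (`icc.tsv`), eligibility and
longitudinal dyslipidemia status with point/periodic prevalence
(`prevalence.json`), family-history odds ratios (`or_table.tsv`),
likelihood and Bayesian heritability tables (`h2_ml.tsv`, `h2_bayes.tsv`,
`report_h2.tsv`), and a manifest with the seed and config hash. On a
simulated cohort with planted genetic share 0.42 plus household share
0.10, the first-measurement (FM) likelihood h² for TC comes out at 0.536
— the pedigree estimate absorbing the household component — and every
average-measurement (AM) h² exceeds its FM counterpart because averaging
phases removes measurement error (e.g. TC 0.630 vs 0.536).

## Layout

```
src/famlipid/
  pedigree.py      kinship, A = 2*phi, pair typing, consanguinity
  phenotypes.py    Friedewald LDL, medication adjustment, ATP III flags,
                   FM/AM scenarios, residualization + inverse normal scores
  cohort.py        exclusions, longitudinal dyslipidemia, prevalence
  history.py       parental exposure, adjusted logistic odds ratios
  correlation.py   double-entry / interclass ICCs, cluster bootstrap
  heritability.py  profile-likelihood (RE)ML, Gaussian/probit Gibbs,
                   Gelman-Rubin, posterior summaries
  simulate.py      pedigree + longitudinal phenotype + disease generator
  cli.py           the `famlipid` pipeline command
```
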