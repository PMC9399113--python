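# famfx — family-based polygenic score designs

`famfx` is a simulation and estimation toolkit for separating **direct** and
**parental indirect** genetic effects on offspring outcomes (e.g. education)
with polygenic scores (PGS) and family data. It is aimed at statistical /
behavioural geneticists who want to study how the three classic
within-family designs behave — and how they are biased — under controlled
generative conditions.

## The designs

All models jointly include a cognitive (Cog) and a non-cognitive (NonCog)
PGS and regress a standardized outcome on them (plus covariates: sex, age,
sex×age, ancestry PCs, platform):

* **Sibling design.** Fit the within/between decomposition
  `y_ij = α + β_W (PGS_ij − P̄GS_j) + β_B P̄GS_j + Z_ij` together with the
  population model `y_ij = α + β_pop PGS_ij + Z_ij` on the same siblings.
  The within-family coefficient β_W is the direct effect (it rests only on
  random Mendelian segregation within families); the parental indirect
  effect is `β_pop − β_W`.
* **Adoption design.** Fit the population model separately in adoptees and
  in non-adopted individuals. Adoptees share no genes by descent with their
  rearing parents, so their PGS effect is a direct effect; the indirect
  effect is `β_pop(non-adopted) − β(adoptees)`.
* **Trio (non-transmitted alleles) design.** From phased parental
  haplotypes build a transmitted composite `PGS_T` (paternal + maternal
  transmitted scores) and a non-transmitted mid-parent composite `PGS_NT`,
  standardize each, and fit
  `y = α + β_T PGS_T + β_NT PGS_NT + Z`. Non-transmitted alleles can act
  only through the rearing environment, so the indirect effect is β_NT and
  the direct effect `β_T − β_NT`.

The simulator (`famfx.simkit`) generates two-generation cohorts of unlinked
biallelic SNPs with exact per-locus transmission bookkeeping, and phenotypes
built from direct, prenatal-parental, postnatal-parental and sibling
components, with optional assortative mating (rank-coupled spouse matching
to a target correlation), Balding–Nichols population stratification with an
ancestry-linked environmental shift, adoptive reassignment, MZ/DZ twins,
and PGS measurement imprecision. `famfx.inference` adds family-level
nonparametric bootstrap (bias-corrected normal CIs), Wald Z contrasts,
random-effects meta-analysis with a design-level random intercept (REML),
and PGS correlation diagnostics (sibling ICC, spousal r).
`famfx.subtraction` provides the two-latent-factor path solver that maps
educational-attainment and cognitive-performance SNP effects onto Cog and
NonCog effects. `famfx.runner` orchestrates scenario grids comparing how
the three designs respond to each bias.

## Worked example

```python
import famfx as fx

scenario = fx.SimulationScenario(n_families=20_000, seed=42,
                                 adoption_fraction=0.2, dz_fraction=0.2)
cohort, weights = fx.simulate_cohort(scenario)
table = fx.cohort_score_table(cohort, weights)
covars = fx.build_covariates(table)

for fit in (fx.sibling_design, fx.adoption_design, fx.trio_design):
    est = fit(table, covariates=covars)
    c = est.estimates["cog"]
    ratio = 100 * fx.ratio(c["indirect"], c["population"])
    print(f"{est.design:9s} population={c['population']:.3f} "
          f"direct={c['direct']:.3f} indirect={c['indirect']:.3f} "
          f"({ratio:.0f}% of population)")
```

prints

```
sibling   population=0.232 direct=0.141 indirect=0.090 (39% of population)
adoption  population=0.240 direct=0.149 indirect=0.091 (38% of population)
trio      population=0.232 direct=0.134 indirect=0.097 (42% of population)
```

The scenario has a true direct effect of 0.15 per SD of the true score and
a postnatal parental effect of 0.2 per unit of mid-parent score, which
implies a population-scale indirect effect of about 0.10; all three designs
recover it (and agree) because this cohort contains no bias components.
With `fx.pgs_correlation_diagnostics(table)` the cohort also shows the
random-mating signatures `sibling PGS ICC = 0.507, spousal PGS r = 0.005`.

The same pipeline is available from the shell:

```bash
famfx simulate --n-families 2000 --seed 1 --out-dir run/
famfx fit --design sibling --scores run/scores.tsv --out run/sibling.json
famfx grid --scale desk --out-dir run/grid && famfx report --results-dir run/grid
```

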