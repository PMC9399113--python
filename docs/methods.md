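# Methods

This note documents the generative model behind `famfx.simkit`, the
estimator conventions in `famfx.scores` / `famfx.designs`, the inference
machinery, and the design choices made where several reasonable options
existed. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Generative model

**Genotypes.** Loci are unlinked, biallelic, and in Hardy–Weinberg
equilibrium within subpopulation. Ancestral allele frequencies are uniform
on `[maf_low, maf_high]` (default 0.05–0.5). With `n_subpops > 1` and
`fst = F > 0`, subpopulation frequencies are Balding–Nichols draws,
`p_s ~ Beta(p(1−F)/F, (1−p)(1−F)/F)`, so `E[(p_s − p)²] = F·p(1−p)`.
Founders (2 per family, equal sexes; subpopulation assigned uniformly per
couple slot) carry two haplotypes of independent Bernoulli(p_s) alleles.
Offspring are produced by independent fair per-locus transmission from each
parent; the transmitted haplotype index is recorded per offspring × locus ×
parent, making transmitted/non-transmitted scores exact rather than
re-inferred. MZ co-twins duplicate one meiosis; DZ co-twins are independent
meioses.

**True scores and phenotype.** Per-SNP true weights for the two constructs
(Cog, NonCog) are independent standard normals; true scores are weighted
allele counts standardized within generation. The offspring outcome is

```
y = Σ_c [ β_direct,c z_child,c + β_prenatal,c midparent_bio,c
        + β_postnatal,c midparent_rear,c + β_sibling,c cosib_c ]
    + strat_env_shift · subpop(own) + ε,   ε ~ N(0, resid_sd²)
```

with `z` the standardized true score, mid-parent the average of the two
parents' `z`, and `cosib` the mean `z` of co-reared siblings (singletons
get no sibling term). Two consequences worth making explicit:

* *Adoption splits the parental channel.* Adoptees keep prenatal effects
  from their biological parents and receive postnatal effects from their
  adoptive parents. Effects between birth and adoption are folded into the
  prenatal component.
* *The stratification shift follows the person's own subpopulation*, not
  the rearing family's. It models an ancestry-correlated environment (the
  fine-scale geographic/social confounding that PC correction targets).
  This is the regime in which an adoptee's PGS–outcome association carries
  the same stratification confound as the population estimate, so the
  adoption contrast cancels it, while the sibling and trio designs subtract
  an (unconfounded) within-family quantity from a confounded population
  quantity and retain the bias. Under the alternative reading (environment
  follows the rearing family) all three designs would be biased equally
  and the well-known robustness ranking of the adoption design would not
  exist.

**Assortative mating.** Spouses are matched within subpopulation by a
Gaussian coupling: each couple slot draws a latent bivariate normal pair
with correlation `am_rho`; males sorted by the mating trait are assigned to
the rank order of the male latent, females to the female latent. This hits
the target spousal correlation on the mating trait to Monte-Carlo accuracy
for any `am_rho ∈ [0, 1)` and reduces to random pairing at 0. One round of
assortment is applied (the disequilibrium regime); no multi-generation
equilibrium is simulated. The mating trait is either the combined true
score `(z_Cog + z_NonCog)/√2` (`mating_trait="pgs"`; the per-construct
spousal correlation is then ≈ `am_rho/2`) or a founder-generation phenotype
built from the direct effects plus noise (`"phenotype"`).

**Adoption.** A fraction of families is selected; one offspring of each is
reared by another selected family via a cyclic shift of a random ordering,
so every rearing family receives exactly one adoptee, never its own child,
and adoptive parents are genetically unrelated to the adoptee. Placement
is random with respect to ancestry and parental traits (no selective
placement).

**Measured scores.** PGS imprecision is modelled at the weight level:
measured weights are `w + b·η̃` where `η̃` is Gaussian noise orthogonalized
against `w` under the genotype-variance inner product `Σ_j a_j b_j 2p_j q_j`
and `b` is chosen so the expected squared correlation between measured and
true scores equals `pgs_precision` exactly. Precision 1 returns the true
weights. This abstracts a finite-sample GWAS into its one consequential
property for the designs — score reliability.

## Estimator conventions

Scores enter each design on its own scale: sibling — standardized on the
sibling sample (non-adopted offspring in families with ≥2 genotyped sibs,
one member of each MZ pair dropped since identical genotypes carry no
within-family information), then decomposed into family mean and deviation;
adoption — standardized within the adoptee and non-adopted groups
separately; trio — transmitted composite `T_pat + T_mat` and non-transmitted
mid-parent composite `(NT_pat + NT_mat)/2` (a summed variant is available;
the two differ only by a factor absorbed by standardization), each scaled to
mean 0/SD 1 over the trio sample. Outcomes are standardized within each
design's analysis sample. On the raw scale the identities
`T_pat + T_mat = own score` and `T_parent + NT_parent = parent's own score`
hold to machine precision, and within-family deviations sum to zero per
sibship; these are asserted in tests for every simulated cohort.

The population model of the adoption design uses one randomly chosen
non-adopted offspring per family by default (an unrelated control sample);
`controls="all"` lets the caller supply a pre-drawn control set. The
sibling design's two regressions use identical rows and covariates so the
subtraction `indirect = population − within` is internally consistent.
Eq-level identities (`direct = β_T − β_NT`, `indirect = pop − direct`,
`indirect = pop − within`) are computed exactly from the fitted
coefficients, never re-estimated.

Ancestry PCs are the left singular vectors of the column-standardized
dosage matrix, fit on one founder per family (unrelateds) and projected
onto everyone, mimicking cohort pipelines; zero-variance SNPs are dropped
with a log line.

**Why score precision matters for the assortative-mating ranking.** With an
exact score and one round of assortment, the sibling and adoption designs'
indirect estimators have algebraically identical large-sample limits (both
inflated by the extra parent–child score covariance). With a noisy score
the two separate: assortment inflates the *between-family* true-score
variance but not the within-family segregation variance or the noise, so
the within-family estimate of the direct effect is attenuated more than the
adoptee-sample estimate, and the sibling design's indirect effect inherits
the difference. The simulation grid therefore runs its bias scenarios at
`pgs_precision = 0.25` (a realistic reliability for current
education-related scores); at precision 1 the assortment scenario would
show no sibling-vs-adoption ordering, which is itself informative and easy
to reproduce by changing one parameter.

## Inference

**Bootstrap.** Ordinary nonparametric, default B = 10,000 (tests use far
smaller B). The resampling unit is the family for sibling/trio designs —
keeping sibships and trios intact, with resampled families relabelled so a
family drawn twice counts as two — and the adoptee / non-adopted strata
separately for the adoption design. One resample feeds every regression
inside a fitter (the sibling design's two models see the same draw).
CIs are bias-corrected normal intervals, centred at `2θ̂ − mean(θ*)` with
half-width `z·SD(θ*)`; percentile intervals are available. Failed
replicates are dropped and counted; >1% failures raise. Derived ratios
(indirect/population, indirect/direct) are propagated through the bootstrap
draws, with ratios guarded when the denominator is numerically zero.

**Meta-analysis.** Two-level REML: marginal covariance
`diag(se² + τ²_within) + τ²_design Z Zᵀ` with a design-indicator Z; the
pooled effect is the GLS mean under the fitted covariance. With a single
design (or `random_intercept=False`) it collapses to a standard
random-effects model, cross-checked against R `metafor::rma(method="REML")`
in the test suite. Variance components are optimized on a square-root scale
by Nelder–Mead from multiple starts. Exact numerical equivalence with a
full multivariate mixed meta-analysis is not claimed.

**Diagnostics.** Sibling ICC is computed by double entry (Pearson r of the
two per-family orderings stacked both ways); the exact finite-sample gap to
the one-way ANOVA ICC is O(1/N) and is verified at that order against both
a direct mean-squares computation and `pingouin`. Spousal correlations are
plain Pearson r; both get Fisher-transform CIs.

## Simulation grid and problem sizes

The bias-comparison grid layers one component or bias at a time on a shared
background (direct 0.15 and postnatal 0.2 per construct, precision 0.25,
two offspring per family with 20% DZ / 10% MZ twin families, 30% of
families contributing one adoptee — the adoptee arm is deliberately
oversampled so the adoption contrast has usable precision, mirroring
equal-sized adoptee/control analysis groups):

| scenario | addition |
|---|---|
| `no_bias` | — |
| `prenatal` | prenatal 0.2 per construct, postnatal 0 |
| `sibling_effect` | co-sibling effect 0.15 per construct |
| `assortment` | spousal coupling 0.75 on the combined score |
| `stratification` | 2 subpopulations, F_ST 0.1, own-subpop shift 1.0 |
| `combined` | all of the above |

Bias settings are intentionally strong so each channel is visible above
replicate noise in a moderate simulation. The runner's presets are
20,000 families × 100 replicates (`full`) and 2,000 × 20 (`desk`); the
acceptance suite runs five scenarios at 3,000 families × 60 replicates,
enough to resolve the smallest contrast (the differential assortment bias,
≈0.01 on the standardized scale) at ≈2.5 standard errors. Parameter-recovery
checks run single cohorts of 20,000 families; the sibling-design
large-sample oracle is a score-level Gaussian simulation (500,000 families)
that bypasses the SNP machinery entirely. Replicates are seeded by a
counter scheme (`SeedSequence([master, scenario, replicate])`), so any
execution order gives identical results and grid outputs are byte-stable.

## Numerical choices

* OLS via `numpy.linalg.lstsq` after a pivoted-QR rank check; rank
  deficiency raises an error naming the collinear columns (verified against
  `statsmodels` to 1e-10). Constant covariates (e.g. a single platform in
  simulation) are dropped with a log line during covariate assembly.
* Standardizing a constant column (all-zero weights, degenerate composites)
  raises a dedicated degenerate-input error rather than producing NaNs.
* Balding–Nichols draws are clipped to (1e-6, 1−1e-6); `fst = 0` bypasses
  the Beta draw so subpopulations are exactly identical.
* Effect-allele alignment: the weight's effect allele defines the counted
  allele; weights on the other allele are negated with the per-haplotype
  constant tracked so raw-score identities survive flips. Strand ambiguity
  is out of scope (simulated alleles are unambiguous).

## What the simulator does not emulate

No linkage or LD (the designs rest on transmission, not linkage), no
multi-generation assortment equilibrium, no selective adoptive placement or
adoptee-specific range restriction, no participation bias, no GWAS
estimation error structure beyond the single reliability knob, no dominance
or gene–environment interaction, and sex/age are pure covariates with zero
true effect unless configured. Passing tests therefore demonstrate the
estimators' behaviour under the stated generative assumptions — they do not
certify behaviour on real cohort data, where these excluded forces (and
phenotype measurement differences between cohorts) operate.

## Known limitations

* The adoption fitter's control group is a simple random one-per-family
  draw; matched-control selection is not implemented.
* The quad (co-sibling) model conditions on two-offspring families and
  treats >2-sib families by the mean co-sibling score; asymmetric older/
  younger sibling effects are not modelled.
* The sibship-size moderation test inherits the generative choice that the
  sibling effect is the *mean* co-sibling score: the own-PGS slope then
  steps up from singletons to any-sibling rather than growing linearly, so
  the linear interaction is an attenuated (but directionally correct)
  summary.
* REML with very few design levels (3) estimates the design-level variance
  noisily; recovery holds on average over many estimate sets, not per fit.
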