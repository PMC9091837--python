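# Methods

`pigekit` implements, end to end, a hemiclone-based test for paternal
indirect genetic effects (PIGEs) on lifespan in *Drosophila melanogaster*:
a Mendelian cross engine for the breeding design, a generative lifespan
model, Bayesian variance-component estimation with a per-draw variance
statistic, a vial-randomization permutation null, and derived PIGE/PTGE
fractions with a haploid-to-diploid correction.

## The breeding design and its transmission genetics

A hemiclone sire carries one intact haploid genome — the X chromosome plus
the two major autosomes, which co-segregate because males do not recombine —
alongside a standardized Y, a T(2;3) translocation of the two major
autosomes marked with the dominant brown-eye allele *bw^D*, and a
standardized 4th "dot" chromosome (<1% of the genome, never varied).

The cross engine enumerates the sire's eight gamete classes (two sex
elements × four autosome segregation products of the translocation
heterozygote, each with probability 1/8).  Crossed to a wild-type dam (one
balanced X-bearing gamete class), half of all zygotes combine an intact
element with a reciprocal fragment and die of aneuploidy; the engine treats
the two unbalanced classes abstractly (`unbalanced_A/B`), because only their
inviability matters downstream.  Surviving sons split exactly 1:1 into

* **PTGE-clones** (paternal total genetic effects): inherit the cloned
  wild-type autosomes, so they express the sire genome's direct *and*
  indirect effects;
* **PIGE-clones**: inherit the marked translocation, are genetically
  standardized across sires (asserted in tests by genotype-signature
  equality), and can differ only through paternal indirect effects.

Crossing a PIGE-clone onward yields **GPIGE-clones** in generation 2, which
probe grandpaternal indirect carryover.  Dams are represented by a
population label only; maternal genetic variance is absorbed into the
residual, and egg-to-adult survival is assumed equal across balanced
genotypes.  Construction of the hemiclone stocks themselves (balancer
crosses) is upstream husbandry and is not simulated.

The packaged design tables reproduce the study sizes: 4 populations ×
(10 vials × 50 PTGE-clones + 20 vials × 50 PIGE-clones) = 6 000 among-population
slots; 2 populations × 20 vials × 50 GPIGE-clones; 38 DGRP lines × 8 vials ×
50 PIGE-clones in 4 blocks (two vials per line per block) = 15 200
within-population slots.

## Generative lifespan model

For sire genome *g* with direct effect *d_g*, indirect effect *i_g*
(bivariate normal, variances `V_D`, `V_I`, correlation `rho_DI`) and
grandsire carryover *gi_g* (variance `V_GI`, default 0, matching the null
grand-offspring finding):

    lifespan = mu + d_g·[PTGE] + i_g·[generation-1 clone] + gi_g·[GPIGE]
             + block offset + vial ~ N(0, V_vial) + residual ~ N(0, V_R)

Defaults (days, days²): `V_I = 3.86` and `V_D = 23.24` so that
`V_D + V_I = 27.10` at `rho_DI = 0`, matching the published among-population
point estimates; `V_I = 2.19` is the within-population default used by the
CLI.  `mu = 50`, `V_vial = 4`, `V_R = 60` are **not** reported quantities —
they were chosen once for a realistic male-lifespan spread (sd ≈ 9–10 d) and
plausible within-vial correlation, and are flagged as such.  Block offsets
are fixed constants (block is a fixed effect in the within-population
model), default zero.

Residuals are Gaussian, not survival-time distributed, because the analysis
models lifespan with Gaussian LMMs; the generator deliberately matches the
analysis model.  Consequences: passing recovery tests demonstrates that the
inference machinery is calibrated *under its own assumptions*; they do not
show robustness to skewed mortality, frailty, or censoring, none of which
the study's design requires (all flies were followed to death).

Death checks discretize the latent time: recorded lifespan is the first
check day at or after death, with a 2/2/3-day repeating pattern ("three
times per week") for the among-population assay and every 2 days
within-population.  Latent times at or below zero (vanishingly rare at the
defaults) record at the first check.

### Conditional-simulation modes for calibration

Two optional moment-matching modes (in the spirit of empirical-covariance
multivariate draws) support calibration studies in which the realized,
not just expected, group contrasts must equal a target:

* `standardize=True` in `draw_genetic_effects` rescales the drawn effects so
  the *sample* variances (denominator k−1) of `i` and `d+i` equal `V_I` and
  `V_D + V_I + 2·rho·√(V_D·V_I)` exactly (and, with `mean_d`, fixes the mean
  direct effect, hence the PIGE−PTGE mean difference).  With few genomes
  (k = 4 populations) the realized among-genome variance would otherwise be
  a highly dispersed χ²-like draw.
* `center_nuisance=True` centres vial effects within each group × clone-type
  cell and residuals within each vial, making realized group means exact.
  This suits models where group is a **fixed** factor: the per-draw variance
  of fixed-level means carries group-mean sampling noise additively (and the
  published estimates carry that same inflation).
* `orthogonalize_group_noise=True` instead conditions the nuisance
  contribution to each group's mean to have exactly its expected variance
  (`V_vial`/vials-per-group + `V_R`/rows-per-group), orthogonal to the
  realized genetic effects.  This suits models where group is a **random**
  factor: the shrinkage estimator implicitly subtracts expected group-mean
  noise, so removing the noise entirely (centring) would bias the statistic
  down by the shrinkage factor, while leaving it unconditioned leaves a
  sampling covariance between effects and noise that dominates
  replicate-to-replicate scatter.

## Variance-component inference

Three models (columns refer to the canonical dataset schema; `group` holds
the population or DGRP line):

| id | formula | used for |
|----|---------|----------|
| M1 | `lifespan ~ group + (1|vial_id)` | among-population V_G(D+I) (PTGE-clones) and V_G(I) (PIGE-clones), fit per clone type; also the GPIGE assay |
| M2 | `lifespan ~ group * clone_type + (1|vial_id)` | joint comparison of V_G(I) with V_G(D+I); clone-type mean difference |
| M3 | `lifespan ~ block + (1|group) + (1|vial_id)` | within-population V_G(I) over 38 lines |

**Sampler.**  Fits use a blocked conjugate Gibbs sampler rather than
Hamiltonian MCMC: the Gaussian LMM with normal priors on location parameters
admits exact full conditionals, and half-Cauchy priors on every scale are
made conjugate through the standard inverse-gamma auxiliary representation
(σ² ~ IG(½, 1/a), a ~ IG(½, 1/A²) ⟺ σ ~ half-Cauchy(A)).  All conditionals
depend on the data only through per-cell sufficient statistics (a cell is a
vial in these nested designs), so one sweep costs O(#vials) and the
hundred-fold permutation refits are cheap.  Inference quality is asserted
against independent oracles (ANOVA method-of-moments and REML via
statsmodels on balanced layouts; brute-force recomputation of the per-draw
statistic) and by parameter-recovery coverage, not by sampler identity.
`target_acceptance` is accepted for interface parity and ignored (no
step-size adaptation exists).

**Budget and priors.**  Defaults: 4 chains × 4000 iterations, first 1000
discarded as warm-up (12 000 retained draws); normal(0, 10) intercept and
normal(0, 2.5) coefficient priors with autoscaling, operationalized as
multiplying the intercept/scale prior sd by sd(y) and each coefficient prior
sd by sd(y)/sd(x_j); half-Cauchy(sd(y)) on vial/line sds and the residual
sd (the scale priors are not stated by the study and are a documented
choice).  The response is centred internally so priors act on the centred
scale; this makes the group-variance statistic exactly location-invariant,
and intercept draws are reported back on the original scale.  Split-R̂
diagnostics (via arviz) are attached to every default fit; values above
1.01 raise a warning, not an error.

**Statistics.**  A variance component is the per-draw `var()` (denominator
k−1) across level means at each retained draw — intercept + coefficients for
a fixed factor (holding the other factor of an interaction at the requested
clone type, which yields the V_G(D+I) posterior at PTGE and the V_G(I)
posterior at PIGE), or the realized level effects for a random factor.  The
residual variance is the per-draw squared residual sd.  Summaries are the
posterior mean with the 95% equal-tailed interval; whether the study's
printed values are means or medians is not stated, so the mean is reported
(the full posterior vector is retained for either).

## Permutation null

Variance components are bounded below by zero, so "significantly larger than
zero" is established by refitting the model K times (default 100; 1000 for
the two-population robustness variant) on data where group labels are
permuted across whole vials — a permutation of the existing label multiset,
preserving per-group vial counts and vial membership, within block when
stratified (the within-population variant).  The observed statistic (the
posterior mean of the per-draw group variance) is significant when it
strictly exceeds at least ⌈0.95·K⌉ null values; ties count against
significance.  Null refits default to a reduced budget (2 chains × 600
iterations) because only point estimates enter the comparison; the result
records this, and the CLI offers `--full-null-budget`.  A null refit whose
chains disagree badly (R̂ > 1.2) is retried with a fresh sub-seed a bounded
number of times.  Under exchangeability the observed rank is uniform among
K+1, so with K = 99 the rule's size is exactly 5/100; the type-I-error
test uses K = 99 with identical observed/null budgets for this reason.

## Derived quantities

From paired posterior vectors of V_G(I) and V_G(D+I) (the M2 fit):

* `pige_fraction` — per-draw V_G(I)/V_G(D+I); draws with non-positive
  denominator are excluded and counted.
* `corrected_fraction` — sires transmit one haploid autosome set (direct
  effects) while their full diploid genome can act indirectly, and autosomes
  are ~80% of the genome, so V_G(I) is multiplied by f = 1 + a = 1.8 before
  recomputing the fraction: f·V_G(I) / ([V_G(D+I) − V_G(I)] + f·V_G(I)).
  Both the mean of per-draw ratios and the formula applied to posterior
  means are reported: plugging the published point estimates into the
  formula gives ≈23.0%, while the published posterior-based value is 22.7% —
  consistent with per-draw computation, and the package reports both rather
  than guessing a single intent.
* `clone_mean_difference` — per-draw PIGE-minus-PTGE contrast of clone-type
  marginal means, averaged over populations (positive = PIGE-clones
  longer-lived).
* `empirical_survival` — pure step functions of the death-check tallies
  (starts at 1, ends at 0; no censoring machinery, since all individuals
  were followed to death).

All ratio posteriors are dimensionless and invariant to rescaling lifespan
units; the correction is non-decreasing in `a` and strictly increasing in
V_G(I) for fixed V_G(D+I) > V_G(I) > 0 (property-tested).

## Reproducibility and problem sizes

Every stage seed derives from one master seed by a stable hash of
(stage name, rep index) reduced mod 2³¹, so full pipeline runs are
bit-reproducible and independent implementations can mirror the structure.
The test suite exercises the full designs where that matters — parameter
recovery runs 20 replicates of the complete 6 000-row among-population
design; the permutation size check runs 120 experiments of a 4-group,
8-vial × 15-fly design at K = 99 with a reduced sampler budget (the
conjugate sampler makes both desk-scale choices, and the statistic's reduced
MC precision cancels between observed and null fits by exchangeability).
The acceptance script re-estimates the headline values at full paper scale
and full sampler budget on conditioned synthetic data, since the archived
experimental data are an external download; what those numbers demonstrate
is that the pipeline is calibrated at the study's exact design and effect
sizes, not that the biological result is re-derived.

## Known limitations

* Gaussian lifespans: no skew, frailty, or interval-censored likelihood;
  the discrete death-check schedule is emulated, but the model treats the
  recorded day as exact (as the analysis models do).
* Maternal genotypes, X-vs-autosome partitioning of indirect effects,
  viability differences among clone types, and meiotic drive are out of
  scope; sex ratio and segregation are exactly Mendelian.
* The per-draw variance of 4 population means is a noisy, slightly inflated
  estimator of the among-genome variance (sampling noise of group means
  enters additively for fixed factors); with k = 4 the realized-variance
  coverage of the 95% CI sits a few points below nominal.  This is a
  property of the statistic at that design size, shared with any
  reimplementation.
* The conjugate sampler requires the Gaussian-LMM structure; it is not a
  general replacement for Hamiltonian MCMC beyond these models.
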