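# Methods

`hympred` implements a genomic-prediction workflow for haplodiploid
insects (parasitoid wasps of the *Nasonia* type), from synthetic data
generation through SNP quality control, genomic relationships, linkage
disequilibrium, REML/GBLUP fitting, and cross-validation. This note
records the models, the defaults and why they were chosen, and the known
limitations.

## The mixed model

The core statistical model is GBLUP with a common-environment (host)
effect and generation-specific residual variances:

    y = X b + Zg g + [0; Zc] c + [e1; e2]

* `g ~ N(0, G σg²)` — additive genomic values for *every* individual in
  the genomic relationship matrix G, phenotyped or not. G is VanRaden's
  Method I, `G = W W′ / 2Σ pj(1−pj)`, with W the allele counts centered
  by `2pj` and `pj` the observed frequency in the pooled genotyped
  cohort ("current population"); a per-generation frequency option
  exists. Missing genotypes are mean-imputed to `2pj` (they contribute
  zero to W); monomorphic loci are dropped from numerator and
  denominator.
* `c ~ N(0, I σc²)` — a host (shared fly-pupa) effect, defined only for
  individuals of the generation whose host identities were recorded.
  Gregarious parasitoids develop in broods inside a single host pupa, so
  brood-mates share a large environmental deviation. Individuals of the
  other generation occupy the zero block of the incidence structure.
* `e1, e2` — independent residuals with separate variances per
  generation. The generation without host records cannot have its host
  variance modelled, so its residual absorbs (part of) it; a pooled
  residual would bias both groups.

Fixed effects default to an intercept plus a generation mean, because
the two sampled generations differ in trait means; an intercept-only
mode is available.

Heritability is reported as `h² = σg² / (σg² + σc² + σe2²)`, i.e. using
the residual of the host-recorded generation, whose phenotypic variance
decomposition is fully modelled.

### REML

Variance components are estimated by restricted maximum likelihood on
the variance-of-y parameterisation `V = σg² A + σc² Zc Zc′ + Σk σek² Dk`
(A is the training submatrix of G, Dk residual-group indicators), using
average-information updates with step-halving, a GCTA-style EM fallback
when the AI step fails to improve the restricted likelihood, and
projection of components onto a small positive floor (10⁻⁶ × var(y)).
Convergence requires a relative log-likelihood change below 10⁻⁸.
Components without support in a data subset are dropped from the
parameter vector rather than pinned at a boundary: a training set
containing only the generation without host records fits no host
component and a single residual.

Small systems (≤ 200 observations) use three starting decompositions
(equal split, residual-heavy, genetic-heavy) and, below ~60
observations, a Nelder–Mead polish on log-components, because the
restricted likelihood of a four-component model on a handful of
observations is genuinely multimodal. Large systems are well conditioned
and use a single start.

G is "bent" (ε = 10⁻⁶ added to the diagonal) when its smallest
eigenvalue falls below 10⁻⁸, keeping V invertible.

GEBVs for all individuals — including those with masked phenotypes —
are `ĝ = σg² G[:, train] P y` with `P y = V⁻¹(y − X b̂)`; host BLUPs are
`ĉ = σc² Zc′ P y`.

## Quality control

The filter cascade mirrors GBS practice: per-site mean read depth in
[9, 300], call rate > 0.80, exact Hardy–Weinberg test p > 10⁻⁴, minor
allele frequency > 0.02, then individuals with *more than* 30% missing
calls over the retained sites are removed (an individual at exactly 30%
is kept). Each removed site is charged to the first criterion it fails,
so the audit partitions the removals; the cascade is site filters first,
individual filter second, with no recomputation loop (an optional
recomputation mode is deliberately not the default). The depth filter
applies to the per-site mean depth by default; a per-genotype mode
(`mask_genotypes_by_depth`) sets out-of-range calls missing instead,
for data carrying FORMAT DP.

The HWE test is the exact conditional test: given the allele counts,
the heterozygote count has probability ∝ `n!/(nAA! nAa! naa!)·2^nAa`,
and the p-value sums the probabilities of all attainable heterozygote
counts no more probable than the observed one (two-sided, no mid-p).
MAF and call rate are computed on non-missing calls only. A threshold
set to its fully permissive value disables its check.

## Linkage disequilibrium

r² is the squared Pearson correlation of allele-count codes between two
same-chromosome loci over their jointly non-missing individuals
(composite LD, the convention for unphased data). Decay with physical
distance x is fitted by least squares to `r² = 1/(1 + p·x)`; the
half-decay distance is `1/p`. The default is one pooled fit over all
pairs; a per-focal-SNP mode fits each focal marker separately and
reports the median rate, since published analyses are ambiguous about
the aggregation. Distances are absolute differences of 1-based
positions.

## Effective chromosome segments and expected accuracy

`Me = 1 / Var(G_ij, i≠j)` (sample variance over each unordered pair
once) and the expected prediction accuracy for a training population of
`Np` unrelated individuals is `ρ = sqrt(Np h² / (Np h² + Me))`. Both the
variance-based `compute_me` and the SD-based `me_from_sd` (for checking
published summaries) are exposed. Family structure makes ρ an upper
bound: sib-groups inflate realized relationships without adding
independent segments.

## Validation

* AGFV/AGBV: deterministic generation splits (train on one generation,
  predict the other).
* K-fold (default k = 5): per repeat, a random partition into near-equal
  folds; every individual is validated exactly once per repeat;
  validation predictions are pooled over the k folds before statistics
  are computed, then repeat-level statistics are averaged (default 50
  repeats; study-sized runs here use 10).

Masked (validation) phenotypes are removed from the observation vector
entirely — tests assert that altering them cannot change training-side
GEBVs. Accuracy is `cor(GEBV, y) / sqrt(h²)` with h² from the full-data
fit by default (a per-fold option exists); the correlation uses raw
observed phenotypes, with an optional fixed-effect-adjusted mode (off by
default). Dispersion is the OLS slope of phenotype on GEBV; 1 is the
theoretically correct scale, above 1 underdispersion, below 1
overdispersion.

## The synthetic-data generator

The generator stands in for a mass-reared laboratory population:

* **Genome.** Five chromosomes of 89.38 cM each (446.9 cM total — the
  per-chromosome split is the package's own even default, only the total
  is anchored), mapped to base pairs at 660 kb/cM so the genome spans
  ~295 Mb. Default 8,639 SNPs placed uniformly at random, proportional
  to map length.
* **Founders.** 472 founder haplotypes with per-locus alternate-allele
  frequencies Uniform(0.05, 0.5) (an arbitrary but serviceable spectrum;
  real founder spectra are unknown) drawn in linkage equilibrium.
* **Burn-in.** 100 discrete generations at effective size 236
  (118 females + 118 males), random mating. LD builds by drift and
  recombination; at equilibrium the expected half-decay scale is
  `c ≈ 1/(4Ne)` ≈ 0.1 cM ≈ 70 kb here — the "slow decay" regime of a
  small closed insect culture (tens of kb).
* **Inheritance.** Haplodiploid: daughters = recombinant maternal gamete
  + the father's entire haploid genome; sons = recombinant maternal
  gamete only. Recombination occurs only in female meiosis, as Poisson
  crossovers (mean = map length / 100) uniform on the cM map, no
  interference.
* **Cohorts.** Two phenotyping cohorts (defaults 717 and 513 females)
  sampled three generations apart. Each cohort is structured into broods:
  one mother × one father per host, brood sizes near-equal and capped at
  60 (the biological clutch limit). Host identities are exported only
  for the second cohort, but host effects act on both — mirroring a
  study design in which earlier collections lacked brood records.
* **Phenotypes.** `y = mean + Σ(QTL dosage × effect) + host + residual`
  with QTL a random subset of segregating SNPs (default 200), normal
  effects, and a normal host effect shared by brood-mates. In the
  default "realized" scaling each component is rescaled so the cohort
  variance decomposition hits the targets exactly (h², host fraction);
  the "expected" mode scales by theoretical factors only. Defaults span
  the observed regimes: a size-like trait (host fraction 0.45) and a
  ratio-like trait (host fraction 0.08), both h² ≈ 0.22.

What the generator does *not* emulate: selection, mutation, sex-ratio
evolution, genotyping error beyond uniform missingness, GBS ascertainment
of marker positions, and real founder haplotype structure. Passing tests
on this data show that the estimation machinery is correct under its own
model assumptions, not that any particular field population satisfies
them.

## A deliberate confounding, documented

In the two-generation design, broods are full-sister groups. Because
haplodiploid fathers pass their entire genome to every daughter, full
sisters have additive relatedness ~3/4 — much higher than diploid full
sibs. For the generation without host records the shared-host covariance
within broods cannot be absorbed by its iid residual, and the only model
term with matching covariance structure is the genomic one: σg² (and
hence the full-data h²) is inflated when generation-1 host variance is
large. This is a property of the study design itself, not of the
implementation — the model equation explicitly leaves generation-1 host
effects unmodelled. Consequences adopted here:

* Parameter-recovery tests run on a fully specified single-generation
  cohort with recorded hosts, where REML recovers (σg², σc², σe²)
  accurately at n = 2,000.
* The dispersion calibration keeps the two-generation design: BLUP is
  self-calibrating against its own REML components, so the phenotype-on-
  GEBV slope remains ≈ 1 even when components are reapportioned.
* Full-data h² from two-generation fits of size traits should be read
  as an upper bound.

The same brood design shapes the 5-fold dispersion slope. "Slope = 1"
is exact only when validation phenotypes are independent of the
training data given the breeding values; when broods are split across
folds, a validation female's host effect is shared with training
sisters, `cov(ĉ, ĝ) > 0`, and the slope is pushed above 1. In the
study-shaped design this is largely cancelled by the σg² inflation
described above (larger σg² → less shrinkage → larger var(ĝ) → smaller
slope), and the realized mean slope sits close to 1 — the same regime
the published 5-fold dispersions occupy. The generator option
`shared_host_effects="recorded"` (host variance individual-level in the
unrecorded generation, the exact generative mirror of the fitted model)
removes the cancelling inflation and exposes the pure shared-host
leakage: there the slope settles around 1.2–1.3 despite the model being
correctly specified. Both modes are available; the calibration study
uses the study-shaped default.

## Problem sizes and numerical defaults

Study-sized runs in the test suite and the acceptance script use a
1,200-female cohort with 2,000 SNPs and 10 cross-validation repeats, and
a 2,000-female single-generation cohort with 500 SNPs for parameter
recovery — sizes chosen so each REML fit stays in the seconds range on
one core while keeping Monte-Carlo error well inside the asserted
tolerances. Degenerate inputs fail loudly and early: extinct simulated
populations, all-monomorphic marker sets, constant GEBVs in the
dispersion slope, constant off-diagonals in Me, zero-variance phenotypes,
and host-generation individuals without host ids are all explicit
errors rather than NaNs.
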