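# Methods notes

## The model and its assumptions

The package targets the classic repeatability GBLUP setting: repeated
records on genotyped cows, a single overall mean as the only fixed effect
(phenotypes are assumed pre-adjusted for contemporary-group effects
upstream), and random animal effects whose covariances come from marker
data. Model A fits breeding values and a permanent-environmental (pe)
effect; model A+D adds dominance deviations:

    y = 1 μ + W u + W d + W pe + e,
    u ~ N(0, G σ²ₐ), d ~ N(0, D σ²_d), pe ~ N(0, I σ²_pe), e ~ N(0, I σ²_e).

All random effects enter through the record→animal incidence `W`. The pe
term is an iid animal effect; with a single record per animal it is
confounded with the residual, which the estimator tolerates (the average-
information matrix is then singular and a pseudo-inverse/EM fallback is
used) but cannot resolve — two or more records per animal are the intended
use, and the simulator defaults to two.

The additive coding `z = x − 2p` and the dominance coding
`m ∈ {−2p², 2pq, −2q²}` are chosen so that under Hardy–Weinberg
proportions each SNP's additive and dominance codes are uncorrelated and
mean-zero (`E[z] = E[m] = E[zm] = 0`, exact algebraic identities tested on
a frequency grid). This makes σ²ₐ and σ²_d estimable without confounding
and puts both matrices on the base-population scale via the denominators
Σ2pq and Σ(2pq)². Allele frequencies default to observed frequencies over
*all* supplied animals (training and validation together — validation
genotypes belong in G/D); a precomputed `AlleleFrequencies` can be passed
to override. Monomorphic SNPs are excluded from numerators, denominators
and from N in the inbreeding coefficient: their per-SNP terms are 0/0 and
any other convention divides by zero.

Two inbreeding measures are reported per animal: the homozygous-SNP
fraction, and G_F — the frequency-standardised self-relationship minus
one, computed with `x` counting the most common allele per SNP. The two
normalisations coincide only when every frequency is 0.5 (then
diag(G) = 1 + G_F exactly, an identity the tests assert at 1e−12); for
general frequencies they weight SNPs differently (common denominator Σ2pq
versus per-SNP 1/2pq) and correlate strongly (r ≈ 0.75–0.8 on HWE
simulations at MAF ≥ 0.05) but not perfectly.

A related subtlety: the additive codes are exactly column-centred at
observed frequencies, so G·1 = 0 identically, but the dominance coding is
quadratic in the allele count and its column sums do not vanish — the
expected mean *row sum* of D is ≈ 1 even for unrelated HWE samples. The
meaningful "relationships average out" property for D is that off-diagonal
(pairwise) entries are mean-zero, and that is what the tests check.

## REML

The restricted likelihood is maximised with 5 EM warm-up iterations
(monotone, safe far from the optimum) followed by average-information
steps with step-halving; if no halved AI step improves the likelihood the
iteration falls back to EM. Components are floored at zero; a component
held at the floor for 3 consecutive iterations is pinned at the boundary
for the rest of the fit and gets no standard error (boundary estimates
have no meaningful curvature-based SE). Convergence requires a relative
LogL change below 1e−8 and a relative component change below 1e−6, with a
200-iteration cap; starting values split the empirical phenotypic
variance equally across components. Standard errors are square roots of
the diagonal of the inverse average-information matrix at the optimum. A
ridge of 1e−8 is added to the covariance diagonal only if a Cholesky
factorisation fails, and is logged.

Computationally, every quantity is evaluated after an exact reduction of
the record-level likelihood: because all random effects act through `W`,
the data split into within-animal contrasts (depending on σ²_e alone,
through the within sum of squares and its degrees of freedom) and animal
means with covariance σ²ₐG + σ²_dD + σ²_peI + σ²_e·diag(1/rᵢ). One
iteration therefore factorises an n_animals matrix instead of an
n_records matrix. This is an algebraic identity, not an approximation;
the tests verify log-likelihoods, gradients (implicitly, through the
optimum) and BLUP solutions against an independently coded dense
record-level implementation at 1e−8.

BLUP solutions at the estimated components are the conditional
expectations û = σ²ₐ G[:, obs] t with t the projected animal-mean
residual; animals present in G/D without records are predicted through
their genomic covariances — exactly how validation animals are handled in
cross-validation. Degenerate inputs are handled explicitly: a constant
phenotype vector returns all components at the zero boundary (the
likelihood is then unbounded and no finite LogL is reported); zero
residual variance with repeated records is rejected as singular.

The model comparison uses the boundary-adjusted likelihood-ratio test:
statistic max(0, 2ΔLogL), reference 0.5·χ²(0) + 0.5·χ²(1), p = 1 at a zero
statistic. Under a true zero dominance variance this test is
conservative-to-correct, which the suite checks empirically (200 null
replicates; rejection at nominal 0.05 must not exceed 0.06).

## What the simulator emulates — and what it does not

`simdata` generates the structure the model assumes, with known truth for
recovery testing:

- **Genotypes.** Sires drawn at HWE with MAF uniform on a configurable
  range (default 0.05–0.5; the counted allele is minor or major with equal
  probability). Each daughter receives one gamete from her sire and one
  population gamete; dams are not materialised. This yields the paternal
  half-sib expectation (mean additive relationship 0.25 within families)
  that the cross-validation design keys on.
- **Effects.** Gaussian per-SNP effects with equal variance before
  rescaling; the a- and d-vectors are rescaled so that the HWE-scale sums
  Σ2pq·aᵢ² and Σ(2pq)²·dᵢ² hit the targets exactly. An optional mean
  dominance effect (directional dominance) induces inbreeding depression:
  truth-level correlations between dominance deviation and homozygosity
  go negative, mirroring what dominance-GBLUP studies report for yield
  traits.
- **Records.** y = μ + BV + DV + pe + e, pe once per animal, e per record.
  All randomness flows from one seed through named substreams; identical
  configs give bit-identical outputs.

Defaults are the package's reference design — 20 sires × 50 daughters,
2000 SNPs, 2 records per cow, components (0.25, 0.05, 0.10, 0.60) on a
unit phenotypic scale, i.e. additive heritability 0.25 and a 5% dominance
share of phenotypic variance, in the range reported for dairy yield
traits.

Deliberately *not* emulated: linkage disequilibrium (every SNP is causal
and independent, so marker-based D captures dominance covariance exactly
— real-data attenuation through r⁴ LD decay is absent), multi-generation
pedigrees, selection, full-sib families, genotyping error and imputation
error. Consequently the simulation-based tests demonstrate correctness of
the estimator and the validation design under the model's own
assumptions, not the magnitude of dominance signal recoverable from real
dairy data.

The data-edit filters ship dairy-plausibility defaults (calving interval
kept in 290–550 days with 551–762 truncated to 551; milk 2000–15000 L,
fat 50–800 kg, protein 45–600 kg) and are configuration-driven. The
national fixed-effects pre-correction on real data is replaced by a
generic OLS adjustment on user-supplied covariates (categoricals
dummy-coded, exactly collinear columns pruned via pivoted QR, residuals
returned); for simulated data an intercept-only adjustment is applied.

## Cross-validation design decisions

- Whole sire families are allocated to folds largest-first into the
  currently smallest fold (seeded random tie-breaks); supplied dam links
  merge families so no predicted cow has daughters in training.
- Variance components are re-estimated inside every training set — no
  information flows from validation phenotypes into the fit.
- The validation comparison value is the per-animal mean of adjusted
  records (the animal, not the record, is the prediction unit).
- Model A is scored by its breeding value, model A+D by its total genetic
  value (correlations with BV, DV and BV+DV are all reported); slopes of
  phenotype on genetic value are tested against 1 with one-sample t
  tests, correlations and MSE across models with classic paired t tests
  over the k folds (k−1 degrees of freedom). Degenerate cases (identical
  fold metrics, zero-variance predictors) are flagged and reported with
  p = 1 rather than NaN propagation.
- Selection re-ranking uses Spearman correlations (midranks for ties)
  within the top 10/25/50/75/100% by the model-A ranking, top fraction
  rounded up, deterministic id-order tie-break; a flag flips the ranking
  direction for smaller-is-better traits such as calving interval.

## Problem sizes used by the test suite

Unit and oracle tests run on 20–80 animals. The simulation-scale checks
use the reference design above for parameter recovery (single replicate,
every component within 3 SEs of truth, and the model-A pe component
absorbing the dominance variance within 10% of the true total), 200
replicates of 300 cows × 500 SNPs for the null calibration of the LRT,
and 1500 cows × 1000 SNPs with a 10% dominance share for the
cross-validation comparison. These sizes were chosen as the smallest
designs at which the respective properties are comfortably identifiable.

## Known limitations

- Single-trait, single fixed effect (the mean). Multi-trait models and
  general fixed-effect design matrices are out of scope.
- One dominance parameterisation (the orthogonal coding above);
  alternative constructions ("classical"/heterosis codings, weighted
  GRMs, sparse approximations) are not implemented and estimates are
  known to depend on that choice.
- Epistasis, genomic partitioning of variance and SNP-effect
  back-solving are not provided.
- The average-information SEs are asymptotic; near boundaries they
  understate uncertainty (boundary-pinned components deliberately get
  none).
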