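# Methods

## The problem

`dupgwas` studies — and provides the machinery to run — a genome-wide
association scan when the phenotype has been measured twice, imperfectly,
on every animal. The motivating setting is a beef-cattle cohort whose
subcutaneous fat depth (P8 site, integer millimetres by ruler) was scored
independently by two teams. Two scans of the *same* cohort, genome and
model, differing only in which measurement is used, quantify directly how
much phenotype measurement error perturbs GWAS results: which SNPs are
significant, where the QTL appear to sit, and how correlated the per-SNP
allele effects are.

## The association model

Each SNP is tested one at a time under the animal model

    y = X β + g b + a + e,   a ~ N(0, A σ²ₐ),   e ~ N(0, σ²ₑ I)

* `y` — phenotype vector (mm): one measurement, their mean, or a trimmed
  subset; optionally 0/1 affected status.
* `X` — fixed effects: intercept, herd nested in breed (a composed
  `breed:herd` factor), and `ssg`, the concatenation of sex and slaughter
  group. Factors are treatment-coded with the first level dropped; empty or
  aliased levels are pruned per analysed subset, and a genuinely
  rank-deficient design raises an error naming the aliased columns.
* `g` — dosage of the reference allele, 0/1/2. The reference allele is the
  one listed first in the genotype file; flipping it flips the sign of `b`
  and nothing else.
* `A` — the numerator relationship matrix from the pedigree (tabular
  method, founders assumed non-inbred), optionally after truncating the
  pedigree to a fixed number of generations above the phenotyped animals.
  Generation depth is counted per individual along ancestral paths, which
  preserves every relationship among the analysed cohort; truncation at the
  limit turns the oldest retained ancestors into founders.

The reported statistic is `t = b / se(b)` from generalised least squares
with `V = σ²ₐ A + σ²ₑ I`, two-sided p from Student t with
`df = n − rank(X) − 1` (the df convention is a package choice; at these
sample sizes it is indistinguishable from alternatives). The GLS is
computed by whitening with `V^(−1/2)` and re-estimating the residual scale
from the whitened fit, so when `σ²ₐ = 0` the result reduces *exactly* to
ordinary least squares — a property the test suite asserts against an
independent OLS oracle.

### Variance components: REML with the spectral shortcut

`V` involves a single structured matrix, so with `A = U diag(s) Uᵀ` the
rotated model is heteroscedastic-diagonal: each REML likelihood evaluation
is O(n) after one O(n³) eigendecomposition. The REML criterion is profiled
down to the variance ratio λ = σ²ₐ/σ²ₑ and maximised by a coarse grid over
log λ ∈ [−12, 12] followed by bounded scalar refinement; the λ = 0 boundary
is always evaluated and wins ties (a flat criterion, e.g. `A = I`, yields
the parsimonious σ²ₐ = 0). Asymptotic standard errors come from the
numeric Hessian of the unprofiled REML log-likelihood.

### P3D versus exact mode

By default the scan runs in P3D mode ("population parameters previously
determined"): variance components are estimated once under the no-SNP null
model and reused for every SNP, making the per-SNP test a pair of matrix
products across the whole panel. `exact` mode re-estimates the components
per SNP with the SNP in the fixed part — the classical per-SNP mixed-model
fit. The two are near-identical in practice; the suite checks Pearson
r ≥ 0.99 between their −log₁₀ p vectors on a 300-animal scan, and they
agree exactly when σ²ₐ = 0.

Missing genotypes are handled by casewise deletion per SNP (consistent
with a one-SNP-at-a-time model); monomorphic SNPs are flagged untested and
excluded from every downstream count.

### Discrete phenotypes

For affected/unaffected status the default test is the Cochran–Armitage
trend test with dosage scores (0, 1, 2), returned as a signed normal
statistic with a two-sided p. Where allele *effects* of a discrete coding
are needed (e.g. to correlate two discrete scans), the linear mixed model
can be run on the 0/1 codes instead; both routes are exposed because the
choice is genuinely open — a plain trend test ignores pedigree structure,
the 0/1 mixed model treats status as a linear trait.

## The synthetic cohort

The generator produces the statistical structure the analysis assumes,
not population-genetic realism:

* **Pedigree** — `n_sires` sires (default 94) across 7 breeds, each with a
  uniform 1–19 offspring sibship by unrelated dams: a multi-breed half-sib
  design averaging ~940 genotyped offspring, the scale at which the whole
  pipeline is exercised. An option adds a founder generation above the
  sires. (The original design had hundreds of sires and sibships up to 95
  at population scale; the defaults reproduce the *genotyped cohort* scale
  so that every stage runs on a desktop.)
* **Genotypes** — biallelic SNPs mapped to 14 chromosomes (default 2 000,
  scalable to array size), founder allele frequencies uniform on
  (0.05, 0.95), gene-dropped through the pedigree. `independent` mode drops
  every locus independently (no LD); `blocks` mode draws founder haplotypes
  from a small pool per chromosome block (default 250 kb, 8 haplotypes) and
  transmits whole blocks, creating the local LD needed for clusters of
  significant SNPs to form around a QTL. In blocks mode the QTL pool
  columns are pinned to the configured allele frequency so a small pool
  cannot lose the QTL allele.
* **Trait** — `y = μ + herd + ssg + Σ g_q·effect_q + a + e` with
  `a ~ N(0, A σ²ₐ)` drawn over the full pedigree via Cholesky. Defaults:
  μ = 11 mm, σ²ₐ = σ²ₑ = 8 mm² (h² = 0.5, matching a moderately heritable
  fatness trait), herd s.d. 1.5 mm, ssg s.d. 1.0 mm, and two linked QTL
  ~1.2 Mb apart on chromosome 14 with effects 1.0 and 0.8 mm per allele —
  effect sizes of the order reported for the major fat-depth QTL.
* **Measurements** — `m_k = round(max(0, y + δ_k + ε_k))` with δ₁ = 0,
  δ₂ = 0.9 mm (the between-team offset; the two field means differed by
  ~0.9 mm). ε is contaminated normal: s.d. 2 mm with probability 0.95,
  s.d. 8 mm otherwise (`blunder_prob = 0.05`) — chosen so that divergence
  is driven by a minority of strongly divergent pairs, which is what the
  field data showed. After rounding, values within ±2 mm of 10 mm are
  attracted to 10 with probability 0.10, emulating digit preference; the
  mechanism (attraction window) is a modelling choice, only the phenomenon
  (excess at 10 mm) is documented in the source data. Errors of the two
  measurements are independent given the truth (two teams scoring
  independently). These defaults land the between-measurement correlation
  near 0.7, the regime of interest; no quantitative error parameters were
  published, so all are exposed and documented here as assumptions.
* **Calibration** — `calibrate_error_sd(r, var_y) = sqrt(var_y (1−r)/r)`
  inverts the classical-error correlation, letting a study target an exact
  repeatability. `config_for_reliability` switches blunders, heaping and
  offset off so that the correlation is governed by this one dial; at
  reliability 1 the two measurements coincide bit-for-bit (both are the
  same rounded truth), so the two scans are identical by construction.

What the generator does *not* emulate: recombination maps and
coalescent/forward LD structure, mutation, selection, genotyping error,
ascertainment of the SNP panel, non-normal residuals. Passing tests
therefore demonstrate the statistical mechanics of measurement error —
attenuation, trimming behaviour, threshold-coding discordance — not the
specific architecture of any real trait.

## Trimming

* `diff1 = (y₁ − y₂)²` (mm²) and `diff2 = diff1 / (0.5 (y₁ + y₂))` (mm)
  quantify the divergence of a pair. Both are available; `diff1` is the
  default (the two select essentially the same animals in practice).
* **Bivariate trimming** retains pairs with divergence *strictly below*
  the threshold ("diff1 < 36" retains |y₁ − y₂| < 6 mm). It is monotone
  (smaller thresholds retain nested subsets) and idempotent.
* **Univariate trimming** removes values strictly below the nearest-rank
  `lower_frac` quantile or strictly above the (1 − `upper_frac`) quantile
  (ranked from the top), each trait independently — the retained sets
  differ per measurement. Ties at the cut are retained: with heaped
  integer data an exact 5% cut is impossible and keeping ties is the
  conservative choice. Because the quantiles are recomputed on whatever
  sample is supplied, re-applying univariate trimming to its own output
  trims further; unlike the fixed-threshold bivariate rule it is not a
  fixed-point operation.
* **Mean of measurements** is the third option: `(m₁ + m₂)/2` per animal,
  excluding animals missing either measurement (half-integer values are
  expected from integer inputs).

## Threshold traits

"Adjusted" phenotypes are `y − X β̂` from the null model — fixed effects
removed, polygenic and residual variation retained. (Whether the original
analysis also subtracted the animal BLUP is not recorded; fixed-effects-only
is the default and `subtract_blup=True` gives the alternative.) Animals
with adjusted value > mean + k·s.d. (default k = 1) are coded affected,
with mean and s.d. computed on the analysed — possibly trimmed — set.
`equalize_affected` reclassifies the excess affected animals of the larger
coding, nearest-to-threshold first (ties by animal id), so both codings
have the same affected count; reclassified animals are flagged. The
concordance table counts the four joint classes (++ / +A / A+ / AA) and
reports percent discordant to one decimal from exact counts.
`drop_discordant` implements the final cleaning step of removing
discordantly coded animals altogether.

## Concordance statistics

* `fpr(n, α, O) = min(100, round(100·n·α/O))` — the expected number of
  significant SNPs under the global null over the observed number, as an
  integer percentage. The cap at 100% covers scans that find fewer hits
  than chance expects; O = 0 leaves the rate undefined (NA). E_p is
  computed from SNPs *tested* by default; pass the array size explicitly
  to reproduce array-based numbers.
* `compare_gwas` correlates per-SNP allele effects and −log₁₀ p over the
  intersection of SNPs tested in both scans (base 10 is a display choice;
  any base gives the same Pearson r), counts shared significant SNPs per
  threshold, and attaches per-scan FPR, region clusters and chromosome
  rankings.
* `region_clusters` chains significant SNPs on a chromosome while
  consecutive ones are ≤ `max_gap` apart (default 1 Mb — regions separated
  by more than that are treated as distinct QTL); each cluster reports its
  span and the total SNPs inside it.
* `chromosome_summary` ranks chromosomes by significant-SNP count (ties to
  the smaller label). The "share" column has no single natural definition,
  so both top-1 and top-n shares are available.
* `expected_r_effects(r) = r²` encodes the empirical attenuation rule: the
  correlation of allele effects between duplicate-measurement scans tracks
  roughly the square of the measurement correlation, which is why
  repeatability below ~0.95 degrades between-study agreement so quickly.
  The rule is an observation to compare against, not an identity — under
  textbook classical error one would expect the effect correlation to track
  r itself for pure-noise SNPs, and the simulator exists partly so users
  can explore which error models produce the squared relation.

## Problem sizes and tolerances

The test and acceptance workloads run at the cohort scale the package
defaults to: ~940 animals × 2 000 SNPs per scan, 10 seeds per simulation
setting, 3 000 SNPs on a single dense chromosome for the two-QTL
resolution study (2-haplotype blocks there, so block SNPs tag a QTL
deterministically). Monte-Carlo checks use 3-standard-error bands or fixed
seeds; algebraic identities (NRM vs recursive kinship, GLS vs OLS, trend
statistic vs textbook formula) are asserted at 1e-8–1e-12. Relationship
matrices are validated as symmetric PSD with diagonals in [1, 2).

## Known limitations

* Exact mode re-fits REML per SNP and is O(panel) times a null fit —
  intended for cross-checks and small panels, not array-scale scans.
* The NRM is built dense; pedigrees beyond ~20k animals would need the
  sparse-inverse (Henderson) construction, which is out of scope.
* The stratified/mixed-model treatment of discrete traits is deliberately
  minimal (trend test or 0/1 linear mixed model); liability-scale
  transformations and ascertainment corrections are not provided.
* FPR is a per-experiment expectation ratio, not an FDR estimate; it
  assumes independent tests when converting α to an expected count.
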