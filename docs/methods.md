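# Methods

## The causal model

Two-sample MR treats genetic variants as instrumental variables. For
variant j, let β_Xj be the true per-allele effect on the exposure (in
phenotype SDs) and β_Yj the true per-allele effect on the outcome
(log-odds for a case-control outcome). Under the instrumental-variable
assumptions, β_Yj = θ·β_Xj for every valid instrument, where θ is the
causal effect of one SD of exposure on the outcome. Pleiotropy breaks
this: β_Yj = θ·β_Xj + α_j with α_j a direct effect. The estimators below
differ in what they assume about the α_j.

Only summary statistics are used: estimates β̂_Xj, β̂_Yj with standard
errors σ_Xj, σ_Yj from two non-overlapping GWAS. Estimation noise on the
two sides is independent by design.

## Harmonization

Tables are joined on variant id. The outcome's effect is re-signed onto
the exposure's effect allele; allele pairs are matched directly or
through reverse complements, so strand-discordant files harmonize
correctly. Exclusions, in fixed precedence:

1. **palindromic** (A/T or C/G on either side) — strand cannot be
   resolved from alleles alone, so these are always dropped; no
   frequency-based strand inference is attempted;
2. **low info** — imputation info < 0.9 on *either* side (the
   symmetric reading; filtering only one side would let poorly imputed
   records through whenever the other file is well imputed);
3. **allele mismatch** — allele sets incompatible under both strand
   readings.

The precedence affects only the drop counters, never retention, and the
counters partition the intersection exactly. Missing centimorgan
positions are imputed as bp/10⁶ (1 cM ≈ 1 Mb), with a warning; this is
coarse but sufficient for a 3 cM independence window when no genetic map
is supplied.

## Instrument selection

Candidates are variants with selection-side p < 5×10⁻⁸. They are visited
in ascending p-value order (ties broken by chromosome, position, then
variant id, making selection deterministic and invariant to input row
order) and a candidate is kept iff no already-kept variant is *both*
within 3 cM (|Δcm| ≤ 3, boundary inclusive) *and* has r² > 0.05 with it.
This is standard greedy clumping. LD is a sparse input table; absent
pairs count as r² = 0, since LD references are sparse and distant pairs
are excluded by the window anyway. Defaults (5×10⁻⁸, 3 cM, 0.05) are the
conventional genome-wide-significance and independence thresholds.

### Variance explained

For a quantitative trait in SD units, instrument j with effect-allele
frequency p_j contributes 2·p_j(1−p_j)·β̂²_j to a unit phenotypic
variance; the reported percentage is 100× the sum. For a binary trait
the same sum is treated as the observed-scale value and rescaled to the
liability scale by the threshold-model factor K²(1−K)²/(z²·P(1−P)), with
K the population prevalence, z the standard-normal density at the (1−K)
quantile, and P the sample case fraction (falling back to K when the
case fraction is unknown). Both steps are approximations — the log-odds
scale is not exactly the observed 0/1 scale — and the quantity is
labelled as approximate accordingly.

## Estimators

With weights w_j = 1/σ²_Yj:

* **IVW**: θ̂ = Σ w_j β̂_Xj β̂_Yj / Σ w_j β̂²_Xj, the weighted
  least-squares slope through the origin. Heterogeneity is
  Q = Σ w_j (β̂_Yj − θ̂ β̂_Xj)². The SE is the fixed-effect SE times
  max(1, √(Q/(J−1))) — a multiplicative random-effects model whose
  dispersion is floored at 1 so under-dispersion never shrinks the SE.
  A `random_effects=False` flag gives the plain fixed-effect SE.
* **Pleiotropy screen / IVW-excluded**: per-variant contribution
  Q_j = w_j (β̂_Yj − θ̂ β̂_Xj)² referred to χ²₁; variant j is excluded
  iff its tail probability is below 0.05/N (N = instrument count), and
  IVW is re-run on the complement. The χ²₁ Q-contribution is one
  reasonable operationalization of "evidence for pleiotropy"; a direct
  outcome-association threshold would be another (see Limitations).
* **Weighted median**: Wald ratios R_j = β̂_Yj/β̂_Xj with first-order
  SEs σ_Yj/|β̂_Xj|; with normalized inverse-variance weights sorted by
  ratio, the estimate is the ratio at which the cumulative weight minus
  half the own weight crosses ½, linearly interpolated between adjacent
  ratios. The SE is the standard deviation of the estimate over a
  parametric bootstrap (β̂'s resampled from N(β̂, σ²) on both sides,
  weights recomputed per replicate; default 1000 replicates; seed
  required, identical seed ⇒ identical result).
* **MR-Egger**: each variant is first oriented so β̂_Xj > 0 (the
  outcome effect re-signed with it) — without a fixed orientation the
  intercept is meaningless. Then weighted least squares of β̂_Y on
  β̂_X *with* intercept, the same random-effects multiplier with J−2
  degrees of freedom. The intercept estimates the average directional
  pleiotropy; its two-sided test at 0.05 is the pleiotropy alarm.

All p-values are two-sided normal. Wald-ratio SEs are first-order; the
second-order correction is deliberately omitted.

## The battery

One cell = one exposure → outcome analysis: harmonize, select
instruments on the exposure side, run all four estimators on the
selected set. The significance flag is attached *only* to the
all-variant IVW slope, tested against α/n_tests; the other three
analyses are sensitivity checks and never drive the flag. n_tests is a
configuration constant (default 42 = 21 traits × 2 directions) rather
than the number of cells actually run, so a partial run keeps the same
threshold as a full battery. The flag is equivalent to
|θ̂/SE| ≥ Φ⁻¹(1 − (α/n_tests)/2); for α = 0.05 and 42 tests that
critical value is 3.24 — note it is not 3.0, which is roughly the
one-sided quantile; the exact two-sided quantile is used throughout.
Per-cell failures (e.g. no genome-wide-significant instrument) are
recorded in the report, not fatal to the battery. The two causal
directions have different data needs, so the battery takes two focal-
outcome tables: a genome-wide one used as outcome in forward cells, and
an instrument-source one used as exposure in reverse cells.

## The synthetic-data generator

Summary statistics are simulated at the estimate level, not from
genotypes: each variant gets a true β_Xj (zero for null SNPs), a true
β_Yj = θβ_Xj + α_j, and published estimates true + N(0, σ²) with the
sampling SE implied by allele frequency and sample size —
σ = 1/√(2p(1−p)n) for a quantitative trait and
σ = 1/√(2p(1−p)n·v(1−v)) (v = case fraction) on the log-odds scale for
a binary one. This gives exact SE control and millisecond runtimes,
which is what calibration studies need.

Defaults emulate the large-biobank regime the pipeline targets:
quantitative exposure with n = 330,000; binary outcome with n = 173,000,
case fraction 0.35, population prevalence 0.15; MAF uniform on
(0.05, 0.5); 10% palindromic variants and 5% with info < 0.9; LD blocks
laid out on a cM map with block starts (cm_span + 1) apart and
within-block SNPs inside 1 cM, every within-block pair listed at
`block_r2`. Instrument strength is parameterized on the z-score scale:
causal |β_Xj| ≈ |N(10, 2)|·σ_Xj by default, so instruments clear
genome-wide significance with high probability, as hits from a GWAS of
that size do. The outcome table's allele representation is randomly
strand-flipped and allele-swapped per variant, so harmonization is
exercised (and its invariances testable) on every simulated pair.

Two modelling choices deserve emphasis:

* **Directional pleiotropy is aligned with the exposure-increasing
  allele**: α_j ~ N(μ, τ²) is applied with the sign of β_Xj. Allele
  labels are arbitrary, so "directional" pleiotropy is only meaningful
  relative to the exposure-raising direction; defining it this way makes
  μ ≠ 0 bias the Wald ratios coherently and produce a nonzero Egger
  intercept, which is the phenomenon the sensitivity analyses exist to
  catch. Balanced pleiotropy is μ = 0, τ > 0.
* **No sample overlap and no LD decay**: exposure and outcome noise are
  independent (true two-sample design), and LD is constant within
  blocks, zero between. Passing tests therefore demonstrate correctness
  of the algorithms and calibration under the stated model, not
  robustness to overlap bias, population structure, or realistic LD.

The truth ledger stores per-variant β_Xj, α_j and flags;
β_Yj = θβ_Xj + α_j holds exactly, so regressing true outcome on true
exposure effects over non-pleiotropic causal variants returns θ to
machine precision.

## Validation studies and problem sizes

The validation module fixes these study designs (only the master seed
varies); the acceptance script and the heavy tests run them as-is:

* *Oracle equivalence*: 1000 random instances of 3–50 variants; IVW and
  Egger against an independently coded weighted-least-squares oracle.
* *Recovery*: θ = 0.2, 150 single-variant blocks, all causal at
  |z| ~ N(10, 2), 300 replicates; mean estimate and 95% CI coverage.
  The residual attenuation of the mean (≈ −0.005) is the expected
  weak-instrument regression dilution at E[z²] ≈ 100, i.e. a factor
  ≈ E[z²]/(E[z²]+1).
* *Type-I error*: θ = 0, same design, 500 replicates, at 0.05 and at
  0.05/42. The random-effects floor makes IVW mildly conservative
  (long-run rate ≈ 0.045).
* *Pleiotropy robustness*: 250 candidate variants with a wide strength
  spread |z| ~ N(12, 8), 40% of causal variants pleiotropic.
  Directional arm: α ~ N(0.04, 0.005²), 200 replicates — the magnitude
  0.04 was chosen by a-priori power analysis to give ≈ 90% Egger
  intercept power at this design (the narrow-strength default leaves
  the intercept nearly unidentified, since all β̂_X cluster at one
  value). Balanced arm: α ~ N(0, 0.01²), 1000 replicates, expecting the
  nominal 5% intercept rejection rate.
* *Selection*: 200 random instances of ≤ 12 variants against a
  brute-force greedy oracle plus exhaustive pair certification.
* *Battery*: 21 simulated traits, both directions (150 SNPs, 30 blocks
  per trait), checking the 42-cell shape and the p-value/critical-z flag
  equivalence.

These sizes keep the full suite under a minute of estimator time while
holding Monte-Carlo error well inside the asserted bands.

## Numerical choices

* Dispersion floored at 1 in the random-effects multiplier; normal
  (not t) reference distributions throughout.
* Greedy selection tie-break: (p, chromosome, position, variant id).
* Window condition inclusive (|Δcm| ≤ 3.0).
* Egger orientation treats β̂_X = 0 as positive (measure-zero case).
* Weighted-median crossing: if the first running value already reaches
  ½ the smallest ratio is returned; bootstrap draws hitting β̂_X = 0
  exactly are nudged to the smallest positive float.
* p-values from the simulator are floored at 10⁻³⁰⁰ to stay inside
  (0, 1]; read-time validation cross-checks p against |β̂/σ̂| in log
  space with 10% relative tolerance.

## Known limitations

* The per-variant pleiotropy screen (χ²₁ on Q contributions) is one of
  several defensible operationalizations; results can differ from
  software that tests direct SNP–outcome association instead.
* Liability-scale variance explained uses the standard threshold-model
  factor on log-odds effects — adequate for small per-SNP effects, not
  exact.
* First-order Wald-ratio SEs understate uncertainty for weak
  instruments; no winner's-curse correction is applied at the
  significance threshold.
* The simulator does not model sample overlap, LD decay, allele
  frequency differences between studies, or population structure; claims
  validated here are about algorithmic correctness and statistical
  calibration under its generative model.
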