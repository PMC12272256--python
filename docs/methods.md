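# Methods

This note records the statistical model the package implements, the
simulation machinery used to validate it, the numerical choices, and
the known limits of both.

## Estimator and variance model

The relatedness score between individuals i and j is the
moment estimator

θ̂ = 1 − ½·(1/m)·Σ_l (x̃ᵢl − x̃ⱼl)², x̃ = (x − 2p̂)/√(2p̂q̂),

computed through the GRM decomposition θ̂ = 1 − (g̃ᵢᵢ + g̃ⱼⱼ − 2g̃ᵢⱼ)/2 in
one O(n²m) pass (`kinship.compute_grm` + `kinship.pair_thetas`). A
naive per-pair evaluator exists in the test suite as the oracle. The
KING-homo estimator (pooled 2pq scaling) is provided for comparison;
the two coincide exactly when all loci share one allele frequency.
Allele frequencies are always estimated in-sample; both estimators are
exactly invariant to which allele is counted at each locus, so no
harmonization step exists.

Two variance models are implemented in `design`:

* **Single-locus (exact).** Genotype pairs follow the six-class
  allele-sharing table (each allele of the second individual copies the
  first's with probability θ, else is an independent Bernoulli(p)
  draw), giving E(θ̂_l) = θ and
  var(θ̂_l) = (1−θ)²/2 + (1−θ)/(4pq). The closed form is checked
  against the brute-force table moments to 1e-12 on a (θ, p) grid.
* **Multiple-loci (asymptotic).** Treating standardized genotypes as
  Gaussian with inter-locus correlations ρ, recursive application of
  Isserlis's theorem gives var(θ̂) = 2(1−θ)²/me with
  me = m²/Σρ². This is the model used for all inference.

### Where the Gaussian asymptotic is known to understate

The Gaussian model replaces the binomial fourth moment by 3. For an
allele-sharing relative pair the *exact* per-locus variance is the
single-locus value above, whose MAF-dependent term (1−θ)/(4pq) is
linear rather than quadratic in (1−θ). Averaged over MAF ~ U(0.05, 0.5)
the exact variance exceeds 2(1−θ)²/me by ≈ 6% at θ = 0, ≈ 30% at
θ = 0.25 and ≈ 85–110% at θ = 0.5 (the copy-mask variance
θ(1−θ)/(2m) adds a further small term). This is a property of *any*
genotype-valued relative generator — every allelic-correlation or
IBD-state scheme reproduces the same six-class table per locus, and no
such scheme has a MAF-independent per-locus variance — so it is a limit
of the asymptotic variance model itself, not of the simulator.
`sim.variance_validation` therefore reports both expectations: the
Gaussian `expected_var` and the exact-binomial
`expected_var_binomial` (average single-locus variance over the chain's
frequencies plus the mask term), the latter tracking the observed
variance at every θ. Consequences for inference are mild where it
matters most: the null (θ = 0) variance is understated by only a few
percent for common variants, which is also why low-frequency variants
(MAF < 0.05) must be removed during QC — the kurtosis term 1/(4pq)
diverges as p → 0.

## Inference

Under unrelatedness θ̂ ~ N(0, 2/me), so Z = θ̂√(me/2) and the upper-tail
p-value uses `scipy.stats.norm.sf` (complementary-error-function
accuracy into the far tail, ~1e-300). The deepest significant
relatedness is θ_δ = z₁₋α√(2/me), δ = log₁∕₂ θ_δ; α defaults to
Bonferroni 0.05/N over all scanned pairs.

Significant pairs are classified by the crossover boundaries where the
two adjacent-degree z-tests — nulls N(θ_t, 2(1−θ_t)²/me) — give equal
p-values: a(3−2a)/(4−3a) with a = 2⁻ᵗ. The t = 0 null has zero
variance, so the duplicate/first-degree split uses the t = 0.1
convention (boundary 0.881). Degrees are unbounded above; negative
scores can never be significant under the one-sided test and are never
classified. The classification z-statistics use the absolute deviation;
for significant pairs lying between the two adjacent expectations the
absolute and directional readings agree.

## Design guidelines

Guideline I inverts the two-error-rate decision problem:
me ≥ 2[(z₁₋α + z₁₋β(1−θₜ))/θₜ]², returned as an integer ceiling (the
unrounded value is exposed for the exact inversion identity
power(me_exact, α, t) = 1 − β). z₁₋β is the (1−β) normal quantile —
1.2816 for β = 0.1 — the only value consistent with the guideline's
inversion. Guideline II is π = Φ((√(me/2)θₜ − z₁₋α)/(1−θₜ)); at
θₜ = 1 (duplicates) the alternative has zero variance and power is a
step function. The simulated-marker budget helper returns
round(3 × me_min): low-LD panels realize me/m just below 1 (≈ 0.978
under the default chain), so a 3× margin guarantees the realized me
meets the minimum.

## Effective number of markers

* `me_direct` — m²/Σr̂² over all column pairs; each off-diagonal r̂² is
  bias-corrected to r̂² − (1−r̂²)/(n−2) by default, since the ~1/n
  inflation of every squared sample correlation visibly understates me
  once m²/n is large. O(nm²), guarded at m ≤ 20,000; primarily the test
  oracle.
* `me_grm` — 1/var(G_off) on unrelated samples, population divisor
  (indistinguishable from the sample divisor at n(n−1)/2 entries),
  sampling SD 2me/n. This estimator is exact in expectation at θ = 0:
  var(g̃ᵢⱼ) involves only second moments, so genotype kurtosis does not
  enter.
* `me_randomized` — for z ~ N(0, Iₙ), E‖(X̃X̃ᵀ/m)z‖² = tr(GRM²), and for
  unrelated samples E[tr(GRM²)] = n + n(n+1)/me; hence
  m̂e = n(n+1)/(L_B − n) with L_B the B-replicate average of the
  quadratic form, computed matrix-free in O(nmB). B = 100 is the
  default (practically sufficient); the reported SD is the delta-method
  value me²·σ_LB/(n²√B) with σ_LB the replicate SD.

## Simulator

Haplotypes follow a first-order Markov chain: locus frequencies drawn
from U(maf_lo, maf_hi), adjacent-pair LD parameterized by Lewontin's
D′ ~ U(lo, hi) and converted to gametic D via the frequency-dependent
bounds (D′·min(p_A q_B, q_A p_B) for D′ > 0; the negative branch is
implemented but exercised only by unit tests). The D′ parameterization
guarantees all four conditional transition probabilities lie in [0, 1].
Genotypes are sums of two independent haplotypes. Defaults — MAF
U(0.05, 0.5), D′ U(0.1, 0.2), n = 2,000, m = 1,000 — are the low-LD
common-variant study conditions used throughout the validation suite;
under them the realized effective marker count is me ≈ 978 at m = 1,000
(me/m ≈ 0.978).

Relative pairs copy individual i's allele per locus per haplotype with
probability θ, taking non-copied alleles from a single independently
sampled background chain haplotype per chromosome. This preserves
single-locus marginals and Hardy–Weinberg proportions, gives
E[θ̂] = θ, and reproduces the six-class table exactly (chi-square
goodness-of-fit in the suite). Two deliberate simplifications: the
copy mask is independent across loci (real IBD is segmental, which
would *increase* the variance of θ̂ beyond both expectations tracked
here), and a copied/background mosaic slightly attenuates the second
individual's own LD (the adjacent-locus correlation of the second
haplotype scales by θ² + (1−θ)²). Passing validation therefore shows
the estimator and variance machinery behave as derived under the
stated generative model; it does not certify the Gaussian variance for
real segmental relatives.

`variance_validation` evaluates observed variance across pairs within a
repeat and a t-interval across repeats (default 95%; a
Bonferroni-adjusted level should be passed when several scenarios are
judged jointly, as the acceptance suite does with four scenarios per
model family).

## Calibration checks and dependence

All-pairs p-value sets are *not* i.i.d.: pairs sharing an individual
are correlated, and in-sample frequency estimation shifts every score
by O(1/n), which is invisible per pair but decisive for a KS test fed
~2×10⁶ dependent values. Uniformity and type-I calibration are
therefore tested on the n/2 disjoint pairs (2k, 2k+1), which are
mutually independent and satisfy the tests' assumptions.

## Problem sizes

The validation suite runs at: me calibration n = 2,000 × m = 1,000
(5 replicates); variance validation 2,000 pairs × 1,000 loci × 10
repeats × 4 relatedness values per model; null calibration n = 2,000 ×
m = 5,000; planted-relative detection two cohorts of 200 with 10
second-degree pairs on m = 3,086 (three times the Guideline-I minimum
at α = 0.05/40,000, β = 0.1). These sizes keep every Monte-Carlo
standard error comfortably below the corresponding acceptance band.

## I/O and QC

PLINK 1 binary (SNP-major BED + BIM/FAM) is read and written natively;
genotypes are counts of the A1 allele with missing preserved. QC drops
loci with min(p̂, 1−p̂) ≤ maf_min (strict inequality, so a boundary MAF
is dropped) and, by default, any locus with a missing call; an opt-in
mean-imputation mode (x̃ = 0) exists for exploratory runs and warns.
Hardy–Weinberg filtering is delegated to upstream tools (e.g. PLINK)
and not reimplemented. VCF/BGEN, dosages, and X-chromosome handling are
out of scope.
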