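# Methods

This note documents the models, estimators, numerical choices and study
designs behind `ilqtl`, and what the simulation-based checks do and do not
establish about real data.

## Breeding scheme and Mendelian expectations

A BC_bF_{s+1} introgression line descends from an F₁ by `b` backcrosses to
the recurrent parent followed by `s` generations of single-seed-descent
selfing. At any biallelic locus the genotype-class probabilities are

    π_H = (1/2)^(b+s)
    π_B = (1/2)^b (1 − (1/2)^s) / 2
    π_A = 1 − π_H − π_B

computed in exact rational arithmetic (`fractions.Fraction`); for b = 1,
s = 3 this is 23/32 : 2/32 : 7/32. Selfing conserves the donor-allele
frequency, which is (1/2)^(b+1) for any s. Genotypes are held internally as
donor-allele dosage (0/1/2, −1 missing).

Missing calls entering the founder-indicator coding are imputed with the
scheme's expected dosage vector (recurrent slot 2 − 2p, donor slot 2p with
p = (1/2)^(b+1)). This preserves the row-sum-2 invariant and is unbiased
under the Mendelian null; it slightly shrinks per-marker signal when data
are missing not at random. The choice is recorded in output metadata.

## Meiosis and the synthetic-data generator

Meiosis follows the Haldane (no-interference) model. Because crossovers are
a Poisson process on the genetic map, founder origin along a gamete is a
Markov chain at marker resolution: the gamete starts on a random parental
haplotype and switches between adjacent markers with probability
r = (1 − e^(−2d))/2 for map distance d Morgans (r = 1/2 across chromosome
boundaries). The generator samples that chain directly, vectorized over all
lines of a population, which is distributionally identical to sampling
Poisson crossover positions and reading them off at the markers. Segment
mosaics (ground truth) are reconstructed from the marker-origin vectors with
breakpoints at inter-marker midpoints, so mosaic resolution equals marker
resolution.

Default genome: 12 chromosomes, 150 cM / 30 Mb each, 400 evenly spaced
markers per chromosome — a desk-scale stand-in for a dense re-sequencing
SNP map. Evaluation studies use sparser maps (42 or 100 markers per
chromosome) chosen for runtime; spacing is stated with each study below.

Phenotypes are `baseline + genetic value + N(0, σ²_e)` per line,
environment and season. The genetic value is the sum of planted QTL
contributions (per-founder additive allele effects, per environment — sign
changes across environments model G×E) and an infinitesimal background:
one vector of per-marker allele-substitution effects **per trait, shared by
all populations of a study** (the founder alleles are the same loci
everywhere), pre-scaled so a line's polygenic value has unit expected
variance and then multiplied by `polygenic_cv × baseline` (default CV 5% of
the environment baseline). σ²_e is set from the realized variance of the
systematic part so the narrow-sense heritability matches the configured
value (defaults 0.5 under stress, 0.6 under normal conditions; a 2%-of-
baseline noise floor covers the degenerate zero-variance and h² = 1 cases).
When yield-component coupling is on (default), the systematic part of GY is
proportional to PN × FGN × TGW / 1000 rescaled to the environment baseline,
so yield correlates with its components as in field data; studies that need
an analytically known PVE switch it off.

Truncation selection keeps the top fraction (or an exact target count) by
phenotype; with two rounds the survivors are re-phenotyped with fresh noise
between rounds (progeny re-testing). Selection history defaults emulate a
three-population program: 63/68/75 lines reduced to 18/18/21.

What the generator does **not** emulate: epistasis, dominance, genotyping
error beyond random missingness, segregation-distorting loci unrelated to
selection, shared field/spatial effects, and multi-season genotype-by-year
structure (seasons differ only in noise). Passing tests therefore show the
estimators behave correctly under an additive, selectively neutral-or-
truncated model — not that real field data meet those assumptions.

## Joint segregation-distortion (MSD) test

Selected lines over-transmit donor segments at loci controlling the
selected trait. For each consensus marker and population p with n_p scored
lines, the donor-dosage sum S_p has null mean n_p μ and variance n_p σ²
(μ = 2·(1/2)^(b+1), σ² = π_H + 4π_B − μ²). The joint statistic is the
stratified score form

    W = Σ_p (S_p − n_p μ)² / (n_p σ²),

with degrees of freedom equal to the number of contributing populations.
The per-population deviation d_p = S_p/n_p − μ is reported with a
goodness-of-fit significance flag; **positive d means donor-allele excess,
i.e. the donor allele was favored by selection** (the package's sign
convention, stated here because latent-scale GLMM signs are not comparable
across software).

Reference distribution: selected populations are small (≈20 lines), where
the χ² approximation to this discrete statistic is visibly anti-conservative
(measured tail inflation ~40% at p = 10⁻³). The scan therefore enumerates
the **exact** null distribution — the dosage-sum pmf is an n-fold
convolution of (π_A, π_H, π_B) — and reports mid-p values
(P(W > w) + ½P(W = w), the standard treatment for discrete tests). Ties in
W are broken lexicographically by the sorted squared and sorted signed
standardized deviations; this refinement is permutation-symmetric in the
populations, leaves W-based inference untouched, and splits the large
probability atoms caused by reflection pairs S = nμ ± k, making null
p-values nearly uniform (largest remaining atom ≈ 0.007 at 3 × 20 lines).
The χ² reference is used automatically above 500 total lines and on request
(`method="chi2"`).

Single-population goodness-of-fit tests merge genotype classes with
expected count < 1 into the adjacent class with the larger expectation and
use df = classes − 1. QTL calling merges significant markers (default
α = 10⁻³; the scan threshold is configurable) within 5 bins of 100 kb on a
chromosome; peaks break ties by lowest p then smallest bin.

## Founder association scan

Model: y = Xβ + Z_k γ_k + ξ + ε with Z_k the n×4 founder allele-inheritance
indicator built from population membership (not from re-clustered
structure), ξ ∼ N(0, σ²_g K), K = (1/2m) Σ_k Z_k Z_kᵀ, ε ∼ N(0, σ²_e I).
X defaults to an intercept plus population indicators.

Variance components are estimated once on the null model by REML: one
spectral decomposition of K, then a bounded scalar search over
log(σ²_g/σ²_e) ∈ [−10, 10] with tolerance 10⁻⁸, comparing the interior
optimum with both boundaries. Each marker is then tested at those fixed
components (a two-step scan): with P the GLS residual projector of the null
covariance,

    γ̂_k = (Z_kᵀ P Z_k)⁺ Z_kᵀ P y,   W_k = γ̂_kᵀ (Z_kᵀ P Z_k) γ̂_k,

referred to χ² with (observed founders − 1) df — 3 when all four founders
segregate; markers with one observed founder are skipped and flagged.
Because rows of Z sum to 2, Z_kᵀPZ_k is rank-deficient by exactly the
all-ones direction whenever X contains an intercept; the Moore–Penrose
inverse (tolerance 10⁻¹⁰) yields the sum-to-zero (centered) effect
estimates. Reported founder effects are therefore contrasts against the
founder mean, which is all the design identifies.

Two deliberate choices:

* **Null-component Wald instead of per-marker locus-variance profiling.**
  Profiling a locus-specific random-effect variance per marker and forming
  the Wald statistic from the shrunken BLUP gives a statistic that is
  *smaller* than the score form whenever the profiled variance is positive,
  which breaks exact χ² calibration under the null and the closed-form
  equivalence with ordinary regression when the polygenic weight is zero.
  The null-component form has both properties exactly and equals the
  profiled form at σ̂²_γ = 0. It is the standard two-step approximation for
  genome scans.
* **Leave-one-chromosome-out (LOCO) kinship by default.** In BC populations
  LD is chromosome-long, so a whole-genome K absorbs much of a tested QTL's
  own signal (measured ≈40% loss of W). LOCO excludes the tested
  chromosome's markers from K. Under a no-genetic-effect null the cost is a
  small genomic-control inflation (λ ≈ 1.03–1.06 measured at n = 200);
  `loco=False` with whole-genome K is exactly calibrated and remains
  available.

PVE of a marker is 100 · var(Z_k γ̂_k)/var(y); it includes the
between-population part of the fitted values and is invariant to affine
rescaling of y. LD blocks merge consecutive significant markers on a
chromosome when bins are ≤ 5 apart and donor-dosage r² ≥ 0.2 (the package's
block definition). The favorable source is the founder with the extreme
estimated effect in the configured direction.

## Validation, pyramiding and group comparison

The interval genotype of two flanking markers represents the QTL genotype;
discordant (recombinant), heterozygous or missing intervals are excluded.
Homozygous classes are compared with **Welch's** unequal-variance t-test —
homozygous classes in small F₂ samples routinely have very different
spreads, so the pooled-variance form is not trusted — and the difference is
reported recurrent-minus-donor. Relative change is
100·(other − reference)/reference, rounded to one decimal in reports.

Pyramiding groups are the favorable-homozygote signatures over the target
QTL; a line must be homozygous at every target to be scorable, and scorable
lines partition into exactly one group. Background recovery is
marker-count-based, (n_A + ½n_H)/(n_A + n_H + n_B) — a physical-length
weighting would differ where marker density varies, which is why the basis
is stated in the output.

Duncan's multiple range test ranks group means and compares every span of p
consecutive ranked means against q(α_p, p, ν)·SE with the stage-dependent
protection level α_p = 1 − (1−α)^(p−1) (α = 0.05 default), studentized-range
quantiles from `scipy.stats.studentized_range`, and the harmonic mean of the
two compared group sizes in the SE (Kramer-style handling of unequal n).
A span whose range is below its critical value is declared homogeneous and
no pair inside it is tested further. The compact letter display is built by
insert-and-absorb; letters are ordered by the best mean they contain, and
the letter partition is invariant to input order.

## Stress indices and correlations

The stress index of a trait is its line-mean value under stress divided by
its value under the control condition; percent reduction is
100·(control − stress)/control, so index + reduction/100 = 1 for the same
pair. Reports round ratios to two decimals and percents to one decimal;
machine output keeps full precision. Correlations are Pearson, on line
means, pairwise-complete with a minimum of three pairs.

## Evaluation study designs and problem sizes

All studies live in `ilqtl.evaluation` and are shared by the test suite and
`scripts/acceptance.py`; every random draw derives from the single seed.

* **MSD calibration**: 200 replicates of three unselected 20-line BC₁F₄
  populations at 1,000 single-marker chromosomes (exactly independent
  markers, as a null requires). Checks the pooled P(p < 0.001) against its
  binomial 99% CI and per-replicate KS uniformity at the 1% level.
* **MSD power**: 100 replicates; populations of 450/450/525 lines carrying
  one drought-yield QTL (equal favorable donor effects, magnitude set by
  closed form to ≈20% PVE under drought at h² = 0.5), two rounds of 20%
  truncation selection to exactly 18/18/21 lines, scan at α = 10⁻³, merge
  window 5 bins; success = a called interval covers the planted position.
  Genome 12 × 100 markers (300-kb spacing); the QTL sits at a genotyped
  marker so interval coverage is well-defined.
* **Association calibration**: 50 replicates, 12 × 42 markers (504),
  populations 67/67/66 (n = 200); y = population means + iid noise — the
  no-marker-effect null. Reports the median genomic-control λ.
* **Association power**: 100 replicates, 12 × 100 markers, n = 200, one
  low-nitrogen yield QTL at which **every donor allele carries an equal
  deficit −b** against the elite recurrent allele — the common situation
  for donor material in an elite background — with b set by closed form to
  a total PVE of 15% at h² = 0.5 (the mean estimated PVE at the locus is
  ≈16%). This pattern keeps the QTL variance within populations (the
  between-population part would be absorbed by the population indicators in
  X) and makes the largest-effect founder unique: the recurrent parent,
  whose centered effect (+0.75b) is three times any donor's. Detection = a
  declared block covers the planted position at p < 10⁻⁴; ranking = the
  block peak's largest-|effect| founder is the recurrent parent.
* **Oracle checks**: kinship vs an O(n²m) double loop on a 5-line toy;
  goodness-of-fit χ² vs direct Σ(O−E)²/E arithmetic; Welch type-I rate over
  10,000 null replicates; mean background recovery of 10,000 unselected
  BC₁F₄ lines vs the closed-form 0.75.

## Numerical details and degenerate inputs

Exact rational arithmetic for Mendelian expectations; REML tolerance 10⁻⁸
with boundary comparison; pinv tolerance 10⁻¹⁰; exact-null key rounding at
10⁻¹⁰ on the statistic scale; a response lying exactly in the column space
of X short-circuits the REML fit (zero residual variance is floored at
10⁻¹²); constant phenotypes give W ≡ 0 in the scan and an error in PVE;
genotype classes with expected count < 1 are merged before goodness-of-fit
tests; selection that would empty a population and all-missing lines raise
errors rather than propagate NaN.

## Known limitations

The MSD exact null assumes lines are exchangeable within a population;
family structure among selected sibs would make it anti-conservative. The
association scan's two-step Wald ignores variance-component estimation
error (small at n = 200, material below n ≈ 50). LD blocks and the 5-bin
merge window are heuristics tied to the ~100-kb bin convention; with very
sparse maps a single causal locus can surface as several blocks. The
generator's phenotypes are additive and Gaussian; count-like traits (PN,
FGN) are truncated at zero rather than modeled as counts.
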