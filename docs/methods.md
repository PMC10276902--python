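# Methods

## Wavelet transform and estimators

The core transform is the circular Haar MODWT in the Percival–Walden
convention: level-1 filters (1/2, −1/2) and (1/2, 1/2), higher levels by
the à-trous recursion with lag 2^(j−1). The effective level-j wavelet
filter has 2^j taps of magnitude 2^−j — each coefficient is half the
difference between two adjacent window means of width 2^(j−1) — and
squared norm 2^−j, so white noise of variance σ² has expected wavelet
variance σ²·2^−j at level j. With these filters the transform conserves
energy exactly: Var(x) = Σ_j mean(W_j²) + Var(V_J), where V_J are the
level-J scaling coefficients. Levels run to J = floor(log2 L); because
chromosome lengths are fixed by the map and the grid step, L is generally
not a power of two and a scaling-variance remainder is reported
explicitly.

Two per-scale variance estimators are provided. The *biased* estimator
averages squared coefficients over all L positions and makes every
decomposition identity exact (used in the reconstruction tests). The
*unbiased* estimator (the default, and the convention for reported
results) drops the first min(L, 2^j − 1) coefficients per level, whose
circular filter support wraps the chromosome end; non-boundary
coefficients are plain linear functionals of in-range data, which is what
makes the estimator unbiased and lets the neutral theory below apply to it
exactly. Under the unbiased estimator the proportions of variance per
scale are normalised to the assembled total so that they still sum to one;
they are then approximations rather than identities.

## Genome-wide combination

Chromosomes are transformed separately and combined with chromosome-length
weights (grid-point counts). Raw per-scale magnitudes average over the
chromosomes where a scale exists; proportions of total variance assign
zero to chromosomes lacking a scale. The among-chromosome component is the
weighted variance of chromosome means about the weighted grand mean, and
the total genomic variance is assembled as the sum of all components,
which equals the population variance of the concatenated signal exactly
under the biased estimator.

For two signals, the per-scale correlation ρ_λ is computed from
coefficients pooled across chromosomes (equivalently, from
length-weighted per-chromosome covariances and variances); pooling is more
stable than averaging per-chromosome correlations at broad scales, where
single chromosomes contribute few coefficients. The scale weight c_λ is
the geometric mean of the two signals' proportions of variance at λ. The
geometric mean is not arbitrary: it is the unique choice for which
Σ_λ c_λ ρ_λ plus the scaling and among-chromosome terms reconstructs the
genome-wide Pearson correlation exactly (biased estimator), since each
contribution then reduces to cov_λ/(σ_x σ_y). A scale with zero variance
in either signal has undefined ρ_λ (reported as missing, never 0) and
contributes 0.

Per-scale R² uses ordinary least squares of pooled non-boundary response
coefficients on predictor coefficients *without an intercept*: wavelet
coefficients are zero-sum by construction, so an intercept would absorb
nothing and cost a degree of freedom; R² is the uncentred statistic.
Scales with fewer than 3 pooled pairs (or no residual degrees of freedom)
are reported missing.

Confidence intervals use the delete-one-chromosome jackknife with
unequal-block weights (Busing et al. 1999 formulation, chromosome length
as block size), reducing to the ordinary jackknife for equal weights.
Intervals are z-based by default (a t option exists) and centred on the
full-data estimate; they are omitted when fewer than 3 chromosomes
contribute to a scale, where the block jackknife is not meaningful.

## Signal preparation

Grids are anchored at the first observed position and never extrapolate.
Linear interpolation is the default for proportion-valued signals; a
`step` (nearest-preceding) mode suits piecewise-constant signals such as
haploid ancestry state. Physical positions are 0-based with half-open
intervals; genetic positions are cumulative Morgans from the chromosome
start. LD-based ρ = 2N_e·r maps are converted to Morgans by regressing
per-chromosome cumulative ρ lengths through the origin on external
crossover-map lengths (a chromosome with zero crossover length must have
zero ρ length, so no intercept); per-interval ρ outliers are capped
(winsorised) at a user threshold before the regression rather than
removed, preserving map coverage. The log-transform offset for
recombination rates defaults to half the smallest positive rate, keeping
zero-rate intervals finite while perturbing positive rates by less than
one doubling.

## Simulator

The simulator is a forward Wright–Fisher model of a single admixture
pulse: a founding pool of 2N(0) haplotypes, exactly round(α·2N(0)) of them
fully introgressed, paired randomly into diploids. Each generation,
parents are drawn with replacement proportionally to fitness (random
mating, selfing permitted), and each gamete receives Poisson(map length in
Morgans) crossovers placed uniformly on the genetic map — no interference,
so inter-locus separation probabilities follow Haldane's function — with
independent assortment across chromosomes. Population size follows an
arbitrary 2N(t) trajectory.

Selection is the linear additive model w_i = 1 − p_i·S·m(t), where p_i is
the individual's diploid dosage of introgressed alleles averaged over the
selected loci and m(t) ∈ [−1, 1] a per-generation schedule (continuous,
early-only, late-onset, and reversal constructors are provided). Fitness
is clamped at zero for user-supplied S·m > 1. Founders reproduce
neutrally: they are pure-ancestry individuals, and the model targets
recombinant hybrids — an F1 (p = 1/2) has fitness 1/2 at S = 1. Selected
loci are placed uniformly on the *physical* map when a recombination map
is supplied (their density per Morgan then scales inversely with the local
rate, which is what couples selection strength to recombination), and
uniformly on the genetic map otherwise.

Internally, ancestry is stored as a (2N × L) matrix over the evenly spaced
output grid loci rather than as per-haplotype junction lists: crossover
positions are drawn continuously and take effect at the first grid locus
to their right, so the probability that two grid loci are separated in a
meiosis is exact, while junction positions extracted for tract output are
quantised to the grid (placed midway between flanking loci). This
representation makes whole-population generations single vectorised array
operations; its cost is that tract lengths are only resolved to the grid
step, so tract-based analyses should use resolutions well below the mean
tract length 1/(t·2α(1−α)) Morgans.

## Neutral expectation of the wavelet variance

For the full-population ancestry-proportion signal, the expected wavelet
variance at level j is the quadratic form of the level's filter
autocorrelation with the two-locus ancestry-frequency covariance
C(d) = ᾱ(1−ᾱ)·[u_t(d) − (1 − u_t(d))/(2N(0) − 1)], where ᾱ is the founder
introgressed fraction and u_t(d) the probability that two lineages, one
per locus, sampled at generation t (same haplotype with probability
1/2N(t)) trace back to the *same founder haplotype*. u_t is computed by
the exact two-state backward chain: per generation the pair separates with
the Haldane probability r(d) = (1 − e^(−2d))/2 and, when apart, rejoins by
coalescence with probability 1/2N of the parental generation. The second
term in C(d) is the hypergeometric correction for a founding pool of fixed
composition (two lineages on *different* founders are slightly negatively
correlated); it vanishes as expected at t = 0 and matters at small 2N. The
formula applies to non-boundary (unbiased-estimator) coefficients, is
valid for arbitrary 2N(t) trajectories, and at d = 0 reduces to the
single-locus drift law Var(p_t) = ᾱ(1−ᾱ)(1 − (1 − 1/2N)^t) for constant N.
Agreement with simulation is verified at 3 Monte-Carlo-SE tolerance in the
test suite.

## Synthetic study conditions used by the tests

The generator's defaults are the conditions the analyses assume: α = 0.5
pulse admixture, S = 1 (F1 fitness 0.5), 10,000 selected loci for
production-scale selection runs, 2⁻¹² Morgan output grids. The test suite
runs reduced but structurally identical configurations chosen to finish on
one CPU:

- drift law: 2N = 100, effectively unlinked locus, t ∈ {5, 20, 100},
  1000 replicates;
- bottleneck vs constant size: one 1-Morgan chromosome at 2⁻⁹ Morgan
  resolution, 2N = 200→2000 vs 2000, 100 replicates, spectra at
  t ∈ {10, 100} compared with theory at 3 SE;
- selection timing: two chromosomes (1.8 and 1.2 Morgans) on a
  deterministic block map alternating 20 Mb at 0.3 and 3.0 cM/Mb (10×
  contrast, the order of magnitude separating human chromosome arms from
  centromeric regions), 2N = 1000, 500 selected loci placed uniformly on
  the physical map, 2⁻¹⁰ Morgan grids. "Broad" scales are the 0.125–0.25
  Morgan levels, which are well populated with coefficients on
  chromosomes of this size; scales within a factor of four of the
  chromosome length rest on a handful of coefficients and are too noisy
  to assert signs on. Continuous selection is checked at t = 20
  (positive broad-scale correlations in ≥ 19/20 replicates); the
  early-only schedule at t = 200 (broad-scale mean positive, fine-scale
  0.002–0.008 Morgan mean indistinguishable from zero, 95% t-intervals
  across 20 replicates).

What the generator emulates: pulse admixture, drift with bottlenecks,
map-level recombination, polygenic directional selection against one
ancestry with time-varying schedules. What it does not: local-ancestry
*inference* error (signals are true ancestry, not HMM calls — so passing
tests say nothing about caller biases at fine scales), continuous
migration or hybrid-zone geography, mutation, dominance or epistasis,
crossover interference, and overlapping generations. Empirical analyses
inherit whatever biases their input calls and maps carry.

## Numerical choices and degenerate inputs

Conservation identities are asserted at 1e−10 (per chromosome) and 1e−8
(genome-wide); the transform itself is exact to rounding. Zero-variance
scales yield missing correlations, never zeros. A recombination map with
zero rate everywhere collapses all genetic positions to zero and is
rejected at gridding (zero span). Requesting more levels than
floor(log2 L) caps with a warning; all-zero fitness raises immediately
with the generation at which viable parents vanished. Random state
derives from a single integer seed per run; matched-seed selected/neutral
pairs share founders and locus placement via a separate placement stream.

## Limitations

Chromosome-length weighting treats the grid-point count as the
information content of a chromosome, which under-weights chromosomes with
disproportionate boundary loss at broad scales. The jackknife is mildly
anti-conservative with few chromosomes (coverage ≈ 0.93 at nominal 0.95
with 8 blocks in white-noise checks). The matrix engine's memory scales
as 2N × total grid loci; at 2⁻¹² Morgan resolution and 2N = 20,000 a
35-Morgan genome occupies ~3 GB, so production-scale runs should coarsen
the grid or subsample output rather than raise resolution further.
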