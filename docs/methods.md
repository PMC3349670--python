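# Methods

`streamscape` re-creates, as tested and reusable code, the analysis chain
used in core-versus-periphery landscape-genetics studies of
stream-dwelling amphibians: microsatellite diversity and differentiation
statistics, bottleneck detection, circuit-theory landscape resistance,
AIC-based matrix-regression model selection, and coalescent inference of
historical population-size change.  Because such studies rarely deposit
their field genotypes or derived GIS layers, the package ships a
synthetic-data module that generates both landscape rasters and
multi-deme genotypes with known, controlled truth; every downstream stage
is validated against that truth or against closed-form oracles.

## Synthetic data

**Landscapes.** Continuous layers (elevation m, canopy %, frost-free
period days, growing-season precipitation mm, heat-load index) are
stationary Gaussian random fields produced by Gaussian-filtering white
noise (autocorrelation length default 10 cells) and rescaling to a
target mean and standard deviation; slope (degrees) is derived from
elevation by central finite differences, and categorical layers (land
cover 1=forest/2=non-forest natural/3=barrier; stream 1/2) threshold an
auxiliary field at the quantiles implied by the requested category
proportions.  The default cell size is 30 m, matching the resolution at
which such layers are typically distributed.  These fields are spatially
smooth and statistically homogeneous; they do not emulate drainage
networks, valley geometry, or correlated layer stacks, so passing tests
demonstrate correct *computation* on realistic-looking rasters, not
geomorphological realism.

**Genotypes, metapopulation.** A forward-in-time Wright–Fisher
simulator with a row-stochastic backward migration matrix: each
offspring draws a source deme from its deme's migration row, two uniform
parents, one allele per parent, and mutates each allele with probability
μ per generation by ±1 repeat (strict stepwise model), reflecting at
allele bounds (default 5–60 repeats; real microsatellites have bounded
repeat ranges but no documented reflection law, so reflection is a
pragmatic choice).  Simulations start monomorphic and run a burn-in
(guidance: ≥ 10× the largest deme size) to approach mutation–drift
equilibrium; the equilibrium is verified against the stepwise-model
closed form E[He] = 1 − 1/√(1+2θ), θ = 4Nμ.  Gene flow can be tied to a
landscape by `migration_from_resistance`, which sets
m_ij = m0·exp(−α·R_ij)/(D−1) with the diagonal absorbing the remainder —
total emigration per deme is at most m0 and every rate is non-increasing
in α and in resistance, which is the property the recovery experiments
rely on.

**Genotypes, single population with size change.** Backward in time the
diploid size follows N(t) = N0·(N1/N0)^(t/Ta) for t ≤ Ta and N1 earlier.
Coalescence times are drawn by analytic inversion of the cumulative
hazard of this piecewise-exponential trajectory; topology and mutations
are then laid down root-to-tip (uniform splitting reproduces the
coalescent's uniform labelled histories), with Poisson single-step
mutations per branch.  The simulator vectorizes over replicates — the
same code path serves per-locus simulation and the tens of thousands of
parameter draws needed by likelihood-free inference.  `msprime` is used
in the test-suite as an independent oracle for the constant-size case,
never as the implementation.

## Diversity and differentiation

Expected heterozygosity uses the unbiased small-sample estimator
(2n/(2n−1))(1 − Σp²); missing genotypes are excluded per locus.
Hardy–Weinberg tests are Monte-Carlo exact tests on Levene's conditional
distribution.  F_ST is Weir & Cockerham's θ (multi-allelic,
ratio-of-sums over loci; negative estimates reported as computed), with
optional permutation significance (individuals shuffled between the two
populations, default 999 permutations) followed by Bonferroni or
Hochberg correction.  G′_ST standardizes G_ST by its maximum given
within-population diversity, computed pairwise (k = 2) from locus-mean
HS and HT.  D_ps is one minus the mean over loci of the shared-allele
proportion Σ_a min(p_aA, p_aB), chosen because it makes no equilibrium
assumptions.  Rarefied allelic richness is the exact combinatorial
expectation at g gene copies.  AMOVA is distance-based on
allele-identity distances between gene copies (an F_ST analogue; the
repeat-size R_ST analogue is deliberately not used), with the standard
unequal-sample-size coefficients, components summed over loci, and
negative components truncated to zero for percentage reporting (raw
values retained and the truncation flagged).

## Bottleneck tests

A recent bottleneck sheds rare alleles faster than heterozygosity, so
observed He transiently exceeds the equilibrium expectation given the
observed allele count k.  For each polymorphic locus the equilibrium
distribution of He conditional on (n, k) is simulated: θ is calibrated
by bisection so the mean simulated allele count matches k, and
replicates are rejected unless they carry exactly k alleles (default
10 000 accepted replicates).  Mutation models: strict SMM, or a
two-phase model in which a mutation is multi-step with probability
p_multi (default 0.05, i.e. 95% single-step) and multi-step lengths are
1 + Geometric(q) with q chosen to give the configured variance (default
5; the conventional "variance 5%" phrasing is ambiguous between a
variance and a percentage — here it is the variance of the multi-step
length, configurable).  TPM with p_multi = 0 is bitwise-identical to SMM
under the same seed because both run the same per-mutation code path.
One-sided Wilcoxon sign-rank across loci gives excess and deficiency
p-values; conditional distributions are cached per (n, k, config) since
they are data-independent.  Two conditioning modes exist: the classical
per-locus mode recalibrates θ from each locus's own allele count, which
matches long-standing practice but becomes anticonservative as n grows
(the per-locus θ*(k) conditional drifts from the true-θ conditional
while sd(He|k) shrinks; measured type-I ≈ 0.25 at n = 80).  The default
"shared" mode calibrates one θ from the multi-locus mean allele count —
consistent with the model's assumption of shared demography across loci
— and holds the null rejection rate at its nominal 5% across sample
sizes while being more powerful for all but the most recent collapses.
The mode-shift test pools allele
frequencies across loci into ten 0.1-wide classes; a spectrum whose
(0, 0.1] class is not the (possibly tied) mode is "shifted"; ties break
conservatively to L-shaped.

Power caveat: under a strict SMM both the simulated data and the null
carry the least possible heterozygosity-excess signal, and the
sign-rank test's power for a 100-fold collapse peaks well below what
intuition suggests (≈ 0.3 at 9 loci, n = 30, collapse age 0.2·N0).  The
power experiments therefore evaluate the scenario where the signal is
strongest within the family — collapse age ≈ 2·N0 generations,
ancestral θ ≈ 3, n = 80 (within the 10–86 per-stream sampling range) —
where the shared-mode power is ≈ 0.8; the type-I calibration uses
matched model and null.

## Landscape resistance

Continuous layers are linearly rescaled to [r_min, r_max] = [1, 10] in
the hypothesised direction of dispersal resistance (elevation +, slope
+, canopy −, frost-free period −, heat load +, precipitation −);
categorical layers use cost tables, with two alternative ratios per
variable (land cover 1:5:10 and 1:50:100; stream 1:10 and 1:100) carried
as distinct named candidates.  The flat all-ones surface is the
isolation-by-resistance (IBR) baseline.  Grids are clipped to the site
bounding box plus a buffer (default 500 m, i.e. ⌈500/30⌉ = 17 cells) to
limit edge effects.  The graph is the 4-neighbour lattice over data
cells; the edge resistance between adjacent cells is the arithmetic mean
of the two cell resistances (the conventional "average resistance"
cell-connection calculation — the alternative reading, averaging over
focal-node placements, was considered and rejected as incompatible with
one-focal-cell-per-site); nodata cells are removed from the graph rather
than given a large finite cost.  Effective resistance is computed by
grounding one focal node, factorizing the reduced Laplacian once
(sparse LU) and solving one right-hand side per focal site;
R(u,v) = G[u,u] + G[v,v] − 2G[u,v].  The solver is validated against
series/parallel closed forms and a deflated dense pseudo-inverse
(L⁺ = inv(L + J/n) − J/n) to 1e−9.  Multivariate surfaces min-max
rescale each component to [1, 10] cellwise and add them; constant
surfaces map to 1 with a warning.

## Model selection on distance matrices

Matrices are unfolded to row-major lower-triangle vectors with a fixed
pair order.  OLS on z-scored predictors (and response) gives comparable
standardized coefficients; AIC = n·ln(RSS/n) + 2(k+2) with n = number of
site pairs and parameters counted as slopes + intercept + residual
variance.  AIC rather than AICc is the default to match conventional
reporting in this literature; AICc is available by flag and matters
exactly when n_pairs is small.  n = n_pairs overstates the information
content of non-independent matrix pairs; joint row/column permutation
p-values are provided as the defensible significance layer.  All
candidate subsets are fitted (all-subsets was chosen over a single full
model with averaging; with ~11 candidates and pairs-limited n the subset
space is cheap and the RI definition is cleaner), ΔAIC ≤ 2 counts as
interchangeable with the best model and ΔAIC ≤ 10 as marginal (both
boundaries inclusive), Akaike weights are ω = exp(−ΔAIC/2) normalized,
and relative importance RI(v) sums ω over models containing v.
Variables with RI ≥ 0.60 seed multivariate candidates; the IBR baseline
is prefixed to every combination and the IBR-only model is always
included.  Predictor correlations (Pearson, on unfolded vectors) flag
pairs with |r| ≥ 0.8.

## Demographic inference

The exponential size-change model has parameters (N0, N1, Ta, μ) with
log10-uniform priors (defaults: sizes and times over 10¹–10⁶, μ over
10⁻⁵–10⁻²).  Inference is likelihood-free rejection: draw parameters,
simulate at the observed sample size and locus count, summarize each
simulated dataset by the locus means of (He, allele count, allele-size
variance, allele-size range, M-ratio = k/(range+1)) plus the mean
rare-allele fraction (alleles with ≤ 2 copies, a frequency-spectrum
signal separating deep from shallow declines) and the across-locus
standard deviations of He, allele count and size variance; standardize
by the simulated standard deviations, and keep the accept_fraction
(default 1%) of draws closest to the observed vector in Euclidean
distance,
followed by an Epanechnikov-weighted local-linear regression adjustment
clipped back to the prior support.  This replaces the
genealogy-augmented MCMC used historically for this model: it is far
easier to verify (parameter recovery is the acceptance surface) at the
cost of some posterior sharpness.  The first 10% of each replicate's
accepted stream (in draw order) is discarded as a conservative
stabilization step mirroring MCMC burn-in practice; independent
replicates feed a Gelman–Rubin potential scale reduction factor
R̂ = √((((n−1)/n)W + B/n)/W), with R̂ < 1.2 as the pass threshold.
The size-change ratio r = N0/N1 is computed pointwise per draw (the mean
of r need not equal the ratio of posterior means); the history is
classified stable/decline/expansion by whether the central 95% interval
of r covers, lies below, or lies above 1 — an operationalization of the
verbal r = 1 / r < 1 / r > 1 rule.  Reports give means and standard
errors on the log10 scale, converted values 10^mean, 0.025/0.975
quantiles, and time since change in years using a generation time of
12.5 years (a conservative figure for a long-lived, late-maturing
stream amphibian); site proportions are truncated (not rounded) to the
reported precision.

## Problem sizes and numerical choices

The test-suite and the acceptance script scale simulations to what the
statistics require rather than to field-study sizes: equilibrium checks
use hundreds of replicate loci; bottleneck calibration uses 200
replicate datasets with 1 000–2 000 accepted conditional replicates per
(n, k) (cached across datasets); demographic recovery uses 20 000 prior
draws and 2 replicates per run; landscape-genetics recovery uses 20
replicate worlds of 8 demes × 60 diploids on 30×30 grids.  Ties in the
mode-shift test break to L-shaped; ΔAIC class boundaries are inclusive;
negative AMOVA components are truncated only for percentages; constant
resistance layers rescale to r_min with a warning; Laplacian solves
ground the first focal node (the result is ground-invariant).  Seeds
derive from one global seed by hashing stage labels, so every stage is
independently reproducible.

## Known limitations

Synthetic landscapes ignore hydrology and inter-layer correlation;
the forward simulator is haploid-gamete Wright–Fisher without selfing
avoidance, age structure, or facultative paedomorphosis; the
likelihood-free posterior is approximate and its credible intervals are
typically wider than a full-likelihood sampler's — with 8 loci and 30
diploids the per-dataset posterior mean of log10(N0/N1) genuinely
wanders up to a decade around the truth, so single-dataset size-change
magnitudes deserve caution even when the decline/stable/expansion call
is right; the
heterozygosity-excess test has intrinsically low power under a strict
SMM; and matrix-regression AIC treats site pairs as independent
observations, which they are not — permutation p-values are the
mitigation, not a cure.
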