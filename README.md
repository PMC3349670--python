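# streamscape

Landscape genetics and historical demography for microsatellite data
from patchily distributed, stream-dwelling organisms — built for
core-versus-periphery comparisons where one asks: *is today's genetic
structure shaped by the current landscape, or by demographic history?*

The package covers the full analysis chain, plus a synthetic-data module
so every stage can be exercised and validated with known truth:

- **`streamscape.synthetic`** — Gaussian-random-field landscape rasters
  (elevation, slope, canopy, climate, categorical land cover / stream
  layers at 30 m cells), forward Wright–Fisher metapopulations with
  stepwise-mutating microsatellites and resistance-driven migration
  (m_ij ∝ m0·e^(−αR_ij)), and single-population coalescent samples under
  exponential size change N(t) = N0·(N1/N0)^(t/Ta).
- **`streamscape.popgen`** — Ho/He (unbiased), Monte-Carlo exact HWE
  tests, Weir–Cockerham F_ST (with permutation significance), Hedrick's
  G′_ST, the shared-allele distance D_ps, rarefied allelic richness
  A_g = Σ_a [1 − C(N−N_a, g)/C(N, g)], three-level AMOVA, and
  Bonferroni/Hochberg correction.
- **`streamscape.bottleneck`** — heterozygosity-excess/deficiency tests
  (SMM and two-phase mutation models, Wilcoxon sign-rank across loci,
  equilibrium He simulated conditional on the observed allele count) and
  the allele-frequency mode-shift test.
- **`streamscape.resistance`** — landscape layers → resistance surfaces
  (linear rescaling to [1, 10] in the hypothesised direction; cost-table
  categories such as land cover 1:5:10 / 1:50:100), 500 m buffer
  clipping, and circuit-theory effective resistance on the 4-neighbour
  lattice via sparse grounded-Laplacian solves; the flat all-ones
  surface is the isolation-by-resistance (IBR) baseline.
- **`streamscape.model_selection`** — matrix regression of genetic
  distance on resistance distance, all-subsets AIC, Akaike weights
  ω = e^(−ΔAIC/2)/Σe^(−ΔAIC/2), relative importance RI(v) = Σ_models∋v ω,
  RI ≥ 0.60 selection into IBR-anchored multivariate surfaces, and
  permutation p-values for matrix non-independence.
- **`streamscape.demography`** — likelihood-free (rejection +
  regression-adjustment) inference of (N0, N1, Ta, μ) under the
  size-change model, the ratio r = N0/N1 with stable/expansion/decline
  classification, Gelman–Rubin convergence diagnostics across replicates,
  and reporting on log10/converted scales with generation-time → years
  conversion.
- **`streamscape.io` / `streamscape.pipeline` / CLI `streamscape`** —
  GenePop and ESRI ASCII grid I/O, missing-data filtering, and a seeded
  end-to-end driver (`simulate → stats → bottleneck → resistance →
  regress → demography`).

## Worked example

Simulate a population that collapsed 100-fold (N0 = 100 today, ancestral
N1 = 10000, decline began 200 generations ago), then re-infer the
history:

```python
from streamscape import synthetic, demography

data = synthetic.simulate_size_change_sample(
    N0=100, N1=10000, Ta=200, mu=1e-3, n=40, n_loci=10, seed=11,
)
priors = demography.PriorSpec({
    "log10_N0": (0.0, 4.0), "log10_N1": (2.0, 6.0),
    "log10_Ta": (0.7, 4.7), "log10_mu": (-3.5, -2.5),
})
post = demography.infer_posterior(
    data, priors, n_sims=20000, accept_fraction=0.01,
    n_replicates=2, seed=2,
)
report = demography.report_table(post, generation_time_years=12.5)
print(report.round(3).to_string(index=False))
print("classification:", report.attrs["classification"])
```

Output:

```
parameter  log10_mean  log10_se  converted  lower_0.025  upper_0.975   years
       N0       1.060     0.658     11.473        1.000      219.105     NaN
       N1       4.233     0.350  17095.844     4145.642    79068.475     NaN
        T       1.633     0.667     42.968        5.012     1146.037 537.104
classification: decline
```

Read: the history is correctly classified as a decline; the posterior
places the ancestral size around 1.7×10⁴ (truth 10⁴) and the current
size one to two orders of magnitude lower, with 95% bounds that bracket
the true N0 = 100 and Ta = 200 (the "years" column converts generations
at 12.5 y/generation).  Point estimates from a rejection-style sampler
are deliberately broad — the credible intervals are the result, not the
means.

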