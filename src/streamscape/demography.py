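"""Historical size-change inference from single-population microsatellites.

The model: a population of current diploid effective size N0 changed
exponentially from an ancestral size N1 starting Ta generations ago
(backward in time ``N(t) = N0 (N1/N0)^(t/Ta)``), with stepwise-mutating
loci at rate mu.  Inference is likelihood-free: parameters are drawn from
log10-uniform priors, data simulated to match the observed sample size and
locus count, and the draws closest to the observed summary statistics in
standardized Euclidean distance are retained, with a local-linear
regression adjustment.  Independent replicates feed a Gelman-Rubin-style
potential scale reduction factor as the convergence/stability diagnostic.
The ratio r = N0/N1 classifies the history: r < 1 decline, r = 1 stable,
r > 1 expansion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _coalescent
from .datasets import GenotypeDataset

PARAMS = ("log10_N0", "log10_N1", "log10_Ta", "log10_mu")

STAT_NAMES = ("het", "k", "size_var", "size_range", "m_ratio")

#: statistics used inside the likelihood-free sampler: the five locus
#: means, the mean rare-allele fraction (alleles with <= 2 copies; a
#: frequency-spectrum signal separating deep from shallow declines), and
#: across-locus dispersions of He, allele count and size variance
ABC_STAT_NAMES = STAT_NAMES + ("frac_rare", "het_sd", "k_sd",
                               "size_var_sd")


# ------------------------------------------------------- summary statistics
def summary_statistics(data: GenotypeDataset, population=None) -> np.ndarray:
    """Mean over loci of (He, allele count, size variance, range, M-ratio).

    He is the unbiased estimator; size variance uses denominator ``n - 1``
    over gene copies; the M-ratio is alleles per occupied repeat-unit span,
    ``k / (range + 1)``.  Monomorphic loci contribute (0, 1, 0, 0, 1) with
    a warning upstream if the whole dataset is monomorphic.
    """
    pop = population or data.populations[0]
    per_locus = []
    for locus in data.loci:
        g = data.genotypes(pop, locus)
        if len(g) == 0:
            continue
        genes = g.ravel().astype(float)
        alleles, counts = np.unique(genes, return_counts=True)
        k = len(alleles)
        n2 = genes.size
        p = counts / n2
        het = (n2 / (n2 - 1.0)) * (1.0 - (p**2).sum())
        rng_span = float(alleles.max() - alleles.min())
        var = float(genes.var(ddof=1))
        per_locus.append((het, k, var, rng_span, k / (rng_span + 1.0)))
    if len(per_locus) < 2:
        raise ValueError("need at least 2 genotyped loci")
    return np.asarray(per_locus, dtype=float).mean(axis=0)


def _abc_statistics(data: GenotypeDataset, population=None) -> np.ndarray:
    """Summary vector for likelihood-free inference (see ABC_STAT_NAMES)."""
    pop = population or data.populations[0]
    per_locus = []
    for locus in data.loci:
        g = data.genotypes(pop, locus)
        if len(g) == 0:
            continue
        genes = g.ravel().astype(float)
        alleles, counts = np.unique(genes, return_counts=True)
        k = len(alleles)
        n2 = genes.size
        p = counts / n2
        het = (n2 / (n2 - 1.0)) * (1.0 - (p**2).sum())
        span = float(alleles.max() - alleles.min())
        per_locus.append((het, k, float(genes.var(ddof=1)), span,
                          k / (span + 1.0), (counts <= 2).sum() / k))
    arr = np.asarray(per_locus, dtype=float)
    if len(arr) < 2:
        raise ValueError("need at least 2 genotyped loci")
    return np.concatenate([arr.mean(axis=0),
                           arr[:, [0, 1, 2]].std(axis=0, ddof=1)])


# ------------------------------------------------------------------ priors
@dataclass
class PriorSpec:
    """Log10-uniform prior bounds per parameter.

    Sizes are diploid individuals, Ta is in generations, mu per locus per
    generation; equal bounds give a point mass.  See ``DEFAULT_PRIORS``
    for the wide defaults (N0, N1, Ta over 10^1..10^6, mu over
    10^-5..10^-2).
    """

    bounds: dict

    def __post_init__(self):
        for name in PARAMS:
            lo, hi = self.bounds[name]
            if not lo < hi:
                if lo == hi:
                    continue  # point mass allowed
                raise ValueError(f"bad bounds for {name}: {lo} >= {hi}")

    def sample(self, rng, size) -> np.ndarray:
        out = np.empty((size, len(PARAMS)))
        for j, name in enumerate(PARAMS):
            lo, hi = self.bounds[name]
            out[:, j] = rng.uniform(lo, hi, size=size) if hi > lo else lo
        return out


DEFAULT_PRIORS = PriorSpec({
    "log10_N0": (1.0, 6.0),
    "log10_N1": (1.0, 6.0),
    "log10_Ta": (1.0, 6.0),
    "log10_mu": (-5.0, -2.0),
})


# ---------------------------------------------------------------- posterior
@dataclass
class DemographicPosterior:
    """Accepted draws of log10(N0, N1, Ta, mu) per replicate."""

    samples: pd.DataFrame  # PARAMS columns + 'replicate'
    n_sims: int
    accept_fraction: float

    def replicate_arrays(self, param) -> list:
        return [g[param].to_numpy()
                for _, g in self.samples.groupby("replicate", sort=True)]


def _simulate_stats(params_log10, n, n_loci, rng, chunk=4000) -> np.ndarray:
    """Summary statistics for each parameter draw (vectorized over draws).

    Each draw simulates ``n_loci`` independent genealogies of ``2n`` genes;
    statistics are averaged over loci.
    """
    R = params_log10.shape[0]
    out = np.empty((R, len(ABC_STAT_NAMES)))
    for start in range(0, R, chunk):
        block = params_log10[start:start + chunk]
        B = block.shape[0]
        N0 = np.repeat(10.0 ** block[:, 0], n_loci)
        N1 = np.repeat(10.0 ** block[:, 1], n_loci)
        Ta = np.repeat(10.0 ** block[:, 2], n_loci)
        mu = np.repeat(10.0 ** block[:, 3], n_loci)
        durations = _coalescent.size_change_durations(
            2 * n, N0, N1, Ta, rng, size=B * n_loci
        )
        alleles = _coalescent.drop_mutations_smm(durations, mu, rng)
        s = _coalescent.allele_summaries(alleles)
        stacked = np.column_stack(
            [s[name] for name in STAT_NAMES + ("frac_rare",)]
        )
        per_locus = stacked.reshape(B, n_loci, -1)
        means = per_locus.mean(axis=1)
        sds = per_locus[:, :, [0, 1, 2]].std(axis=1, ddof=1)
        out[start:start + B] = np.column_stack([means, sds])
    return out


def _regression_adjust(accepted, stats_acc, obs_std, dist):
    """Beaumont-style local-linear adjustment with Epanechnikov weights."""
    delta = dist.max()
    if delta <= 0:
        return accepted
    w = 1.0 - (dist / delta) ** 2
    w = np.clip(w, 1e-8, None)
    X = np.column_stack([np.ones(len(dist)), stats_acc - obs_std])
    Wsq = np.sqrt(w)[:, None]
    adjusted = accepted.copy()
    for j in range(accepted.shape[1]):
        beta, *_ = np.linalg.lstsq(X * Wsq, accepted[:, j] * Wsq[:, 0],
                                   rcond=None)
        adjusted[:, j] = accepted[:, j] - (stats_acc - obs_std) @ beta[1:]
    return adjusted


def infer_posterior(data: GenotypeDataset, priors: PriorSpec = None,
                    n_sims=20000, accept_fraction=0.01, n_replicates=5,
                    seed=None, population=None, adjust=True,
                    ) -> DemographicPosterior:
    """Likelihood-free rejection inference of the size-change model.

    Per replicate: ``n_sims`` prior draws are simulated at the observed
    sample size and locus count; the ``accept_fraction`` closest draws in
    standardized summary-statistic distance are accepted; a local-linear
    regression adjustment (clipped back to the prior support) sharpens the
    posterior; the first 10% of each replicate's accepted stream (in draw
    order) is discarded as a conservative stabilization step.  Replicates
    are independent and feed :func:`psrf`.
    """
    if n_sims < 1000:
        raise ValueError("n_sims >= 1000 required for meaningful output")
    priors = priors or DEFAULT_PRIORS
    pop = population or data.populations[0]
    obs = _abc_statistics(data, pop)
    n = int(round(np.mean([
        len(data.genotypes(pop, locus)) for locus in data.loci
    ])))
    n_loci = data.n_loci
    rng = np.random.default_rng(seed)
    frames = []
    for rep in range(n_replicates):
        draws = priors.sample(rng, n_sims)
        stats = _simulate_stats(draws, n, n_loci, rng)
        sd = stats.std(axis=0)
        sd[sd == 0] = 1.0
        z = stats / sd
        obs_z = obs / sd
        dist = np.sqrt(((z - obs_z) ** 2).sum(axis=1))
        n_keep = int(round(accept_fraction * n_sims))
        if n_keep < 1:
            raise ValueError("accept_fraction too small: zero accepted draws")
        order = np.argsort(dist, kind="stable")[:n_keep]
        if dist[order[0]] > np.sqrt(len(ABC_STAT_NAMES)) * 10:
            import warnings
            warnings.warn(
                "observed statistics far outside simulated support "
                f"(min distance {dist[order[0]]:.2f})"
            )
        order_stream = np.sort(order)  # draw order = the accepted stream
        accepted = draws[order_stream]
        if adjust:
            accepted = _regression_adjust(
                accepted, z[order_stream], obs_z, dist[order_stream]
            )
            for j, name in enumerate(PARAMS):
                lo, hi = priors.bounds[name]
                accepted[:, j] = np.clip(accepted[:, j], lo, hi)
        burn = int(math.floor(0.10 * len(accepted)))
        accepted = accepted[burn:]
        frame = pd.DataFrame(accepted, columns=list(PARAMS))
        frame["replicate"] = rep
        frames.append(frame)
    samples = pd.concat(frames, ignore_index=True)
    return DemographicPosterior(samples, n_sims, accept_fraction)


# ------------------------------------------------------------- summaries
@dataclass
class SizeChangeSummary:
    r_samples: np.ndarray
    classification: str
    r_interval: tuple
    posterior: DemographicPosterior = None


def size_change_summary(posterior: DemographicPosterior,
                        interval=0.95) -> SizeChangeSummary:
    """Pointwise ratio r = N0/N1 per draw and its classification.

    Classified ``stable`` when the central credible interval of r covers
    1, ``decline`` when it lies below 1, ``expansion`` above.  (The
    pointwise ratio's mean need not equal the ratio of posterior means.)
    """
    s = posterior.samples
    if s.empty:
        raise ValueError("empty posterior")
    r = 10.0 ** (s["log10_N0"].to_numpy() - s["log10_N1"].to_numpy())
    alpha = (1.0 - interval) / 2.0
    lo, hi = np.quantile(r, [alpha, 1.0 - alpha])
    if hi < 1.0:
        label = "decline"
    elif lo > 1.0:
        label = "expansion"
    else:
        label = "stable"
    return SizeChangeSummary(r, label, (float(lo), float(hi)), posterior)


def psrf(replicate_samples, threshold=1.2) -> pd.DataFrame:
    """Gelman-Rubin potential scale reduction factor per parameter.

    ``R_hat = sqrt((((n-1)/n) W + B/n) / W)`` with within-replicate
    variance W and between-replicate variance B (n draws per replicate).
    ``replicate_samples`` maps parameter name -> list of per-replicate
    arrays.  Convergence passes when R_hat < threshold.
    """
    rows = []
    for name, chains in replicate_samples.items():
        chains = [np.asarray(c, dtype=float) for c in chains]
        if len(chains) < 2:
            raise ValueError("PSRF needs at least 2 replicates")
        n = min(len(c) for c in chains)
        if n < 10:
            raise ValueError("replicates too short for PSRF")
        arr = np.stack([c[:n] for c in chains])
        W = arr.var(axis=1, ddof=1).mean()
        B = n * arr.mean(axis=1).var(ddof=1)
        if W <= 0:
            rhat = 1.0
        else:
            rhat = float(np.sqrt(((n - 1) / n * W + B / n) / W))
        rows.append((name, rhat, bool(rhat < threshold)))
    return pd.DataFrame(rows, columns=["parameter", "psrf", "converged"])


def convergence_report(posterior: DemographicPosterior,
                       threshold=1.2) -> pd.DataFrame:
    return psrf(
        {p: posterior.replicate_arrays(p) for p in PARAMS},
        threshold=threshold,
    )


# ------------------------------------------------------------- reporting
GENERATION_TIME_YEARS = 12.5  # conservative: predicted 20-year lifespan


def report_table(posterior_or_summary, generation_time_years=12.5
                 ) -> pd.DataFrame:
    """Size-change report: log10 and converted scales, intervals, years.

    Per parameter: posterior mean and s.e. (posterior standard deviation)
    on the log10 scale, the converted value ``10**mean``, 0.025/0.975
    quantile bounds on the converted scale; the time since change is also
    expressed in years (generations x generation time, default 12.5 y).
    """
    summary = (posterior_or_summary
               if isinstance(posterior_or_summary, SizeChangeSummary)
               else size_change_summary(posterior_or_summary))
    s = summary.posterior.samples
    rows = []
    for name, label in (("log10_N0", "N0"), ("log10_N1", "N1"),
                        ("log10_Ta", "T")):
        x = s[name].to_numpy()
        mean = float(x.mean())
        se = float(x.std(ddof=1)) if len(x) > 1 else 0.0
        lo_q, hi_q = np.quantile(x, [0.025, 0.975])
        converted = 10.0 ** mean
        row = {
            "parameter": label,
            "log10_mean": mean,
            "log10_se": se,
            "converted": converted,
            "lower_0.025": 10.0 ** lo_q,
            "upper_0.975": 10.0 ** hi_q,
        }
        if label == "T":
            row["years"] = years_since_change(converted,
                                              generation_time_years)
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["r_mean"] = float(summary.r_samples.mean())
    out.attrs["classification"] = summary.classification
    return out


def years_since_change(generations, generation_time_years=12.5) -> float:
    """Convert generations to years; e.g. 67920 generations x 12.5 = 849000."""
    return float(generations) * float(generation_time_years)


def percent_smaller(value, reference) -> float:
    """How much smaller ``value`` is than ``reference``, rounded percent.

    ``percent_smaller(2138, 34995) -> 94`` (a 94% smaller ancestral size at
    the range periphery than at the core, in the worked regional example).
    """
    return round(100.0 * (1.0 - value / reference))


def proportion_pct(count, total, decimals=1) -> float:
    """Site proportion as a percentage truncated to ``decimals`` places.

    Truncation (floor) reporting, so 5 of 13 sites -> 38.4 and 2 of 20
    -> 10.0.
    """
    pct = 100.0 * count / total
    factor = 10.0 ** decimals
    return math.floor(pct * factor + 1e-9) / factor


def discard_and_thin(stream, burn_in_fraction=0.10, thin_interval=1):
    """Drop the first fraction of a sample stream, keep every k-th after.

    Length 100 with fraction 0.1 and thin 10 keeps 9 elements.
    """
    if thin_interval < 1:
        raise ValueError("thin_interval must be >= 1")
    stream = np.asarray(stream)
    if not 0 <= burn_in_fraction < 1:
        raise ValueError("burn_in_fraction must be in [0, 1)")
    burn = int(math.floor(burn_in_fraction * len(stream)))
    if burn >= len(stream):
        raise ValueError("stream shorter than burn-in")
    return stream[burn:][::thin_interval]
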