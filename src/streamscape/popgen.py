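"""Diversity and differentiation statistics for microsatellite data.

Heterozygosities (unbiased Nei-style), Monte-Carlo exact Hardy-Weinberg
tests, Weir-Cockerham theta (F_ST), Hedrick's standardized G'_ST, the
shared-allele distance D_ps, rarefied allelic richness, three-level AMOVA
on allele-identity distances, and multiple-testing correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .datasets import GenotypeDataset, PairwiseMatrix


# ------------------------------------------------------------ primitives
def _pop_locus(data: GenotypeDataset, population, locus):
    """(n_genotyped, allele->freq, allele->het carrier proportion)."""
    g = data.genotypes(population, locus)
    n = len(g)
    if n == 0:
        return 0, {}, {}
    alleles, counts = np.unique(g.ravel(), return_counts=True)
    freqs = dict(zip(alleles.tolist(), (counts / (2 * n)).tolist()))
    het = {}
    is_het = g[:, 0] != g[:, 1]
    for a in alleles.tolist():
        het[a] = float(((g == a).any(axis=1) & is_het).mean())
    return n, freqs, het


def unbiased_he(freqs: dict, n: int) -> float:
    """Nei-style unbiased expected heterozygosity, (2n/(2n-1))(1 - sum p^2)."""
    s = sum(p * p for p in freqs.values())
    return (2 * n / (2 * n - 1.0)) * (1.0 - s)


# --------------------------------------------------------- locus summaries
def locus_summaries(data: GenotypeDataset) -> pd.DataFrame:
    """Per population x locus: n, allele count, Ho, unbiased He.

    Missing genotypes are excluded from denominators; a population with no
    genotyped individuals at a locus is reported with ``n = 0`` and NaN
    statistics rather than fabricated values.
    """
    rows = []
    for pop in data.populations:
        for locus in data.loci:
            g = data.genotypes(pop, locus)
            n = len(g)
            if n == 0:
                rows.append((locus, pop, 0, 0, np.nan, np.nan))
                continue
            alleles = np.unique(g.ravel())
            ho = float((g[:, 0] != g[:, 1]).mean())
            freqs = {a: c for a, c in zip(*np.unique(g.ravel(),
                                                     return_counts=True))}
            freqs = {a: c / (2 * n) for a, c in freqs.items()}
            rows.append((locus, pop, n, len(alleles), ho,
                         unbiased_he(freqs, n)))
    return pd.DataFrame(
        rows, columns=["locus", "population", "n", "Na", "Ho", "He"]
    )


# ------------------------------------------------------------------- HWE
def _log_genotype_prob(g: np.ndarray) -> float:
    """Log conditional probability terms that vary with the pairing.

    Under Levene's conditional distribution given allele counts,
    ``log P = h*log 2 - sum log(n_ij!) + const``; the constant cancels in
    comparisons.
    """
    pairs = np.sort(g, axis=1)
    _, counts = np.unique(pairs, axis=0, return_counts=True)
    h = int((g[:, 0] != g[:, 1]).sum())
    return h * np.log(2.0) - gammaln(counts + 1.0).sum()


def hwe_test(data: GenotypeDataset, population, locus, n_reps=1000,
             seed=None) -> float:
    """Monte-Carlo exact Hardy-Weinberg test for one population x locus.

    Gene copies are permuted into genotypes conditional on the observed
    allele counts; ``p = (1 + #{replicates with probability <= observed})
    / (n_reps + 1)``.  A monomorphic locus has ``p = 1`` by definition.
    """
    g = data.genotypes(population, locus)
    if len(g) == 0:
        raise ValueError(f"no genotyped individuals for {population}/{locus}")
    if len(np.unique(g.ravel())) < 2:
        return 1.0
    rng = np.random.default_rng(seed)
    obs = _log_genotype_prob(g)
    pool = g.ravel().copy()
    hits = 0
    for _ in range(n_reps):
        rng.shuffle(pool)
        sim = _log_genotype_prob(pool.reshape(-1, 2))
        if sim <= obs + 1e-12:
            hits += 1
    return (1 + hits) / (n_reps + 1)


# ---------------------------------------------------------- Weir-Cockerham
def _wc_components(data: GenotypeDataset, pops, locus):
    """Per-allele (a, b, c) variance components at one locus."""
    stats = [_pop_locus(data, p, locus) for p in pops]
    if any(n == 0 for n, _, _ in stats):
        return None
    r = len(pops)
    n_i = np.array([s[0] for s in stats], dtype=float)
    alleles = sorted(set().union(*(s[1] for s in stats)))
    if len(alleles) < 2:
        return []  # monomorphic across these pops: no information
    nbar = n_i.mean()
    n_c = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    out = []
    for allele in alleles:
        p_i = np.array([s[1].get(allele, 0.0) for s in stats])
        h_i = np.array([s[2].get(allele, 0.0) for s in stats])
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        a = (nbar / n_c) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
            / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        out.append((a, b, c))
    return out


def fst_wc(data: GenotypeDataset, pop_a, pop_b) -> float:
    """Multi-allelic Weir-Cockerham theta between two populations.

    Ratio of sums over loci and alleles; negative estimates are reported
    as computed.
    """
    num = den = 0.0
    shared = 0
    for locus in data.loci:
        comp = _wc_components(data, [pop_a, pop_b], locus)
        if comp is None:
            continue
        shared += 1
        for a, b, c in comp:
            num += a
            den += a + b + c
    if shared == 0:
        raise ValueError(f"no shared genotyped loci for {pop_a}, {pop_b}")
    return num / den if den != 0 else 0.0


def fst_permutation_p(data: GenotypeDataset, pop_a, pop_b, n_perm=999,
                      seed=None) -> float:
    """One-sided permutation p-value for theta > 0.

    Individuals are shuffled between the two populations, keeping sizes.
    """
    sub = data.subset(populations=[pop_a, pop_b])
    obs = fst_wc(sub, pop_a, pop_b)
    labels = sub.individuals["population"].to_numpy().copy()
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(labels)
        perm = GenotypeDataset(
            sub.individuals.assign(population=labels), list(sub.loci),
            sub.calls,
        )
        if fst_wc(perm, pop_a, pop_b) >= obs - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)


# ------------------------------------------------------------------ G'_ST
@dataclass
class GstComponents:
    HS: float
    HT: float
    GST: float
    k: int


def gst_hedrick(data: GenotypeDataset, pop_a, pop_b):
    """Hedrick's standardized G'_ST between two populations.

    Components are computed from sample allele frequencies, averaged over
    loci (locus-mean HS and HT), then
    ``G'_ST = GST * (k - 1 + HS) / ((k - 1) * (1 - HS))`` with ``k = 2``.
    Returns ``(GstComponents, gprime)``; ``gprime`` is NaN when HS = 1.
    """
    hs_list, ht_list = [], []
    for locus in data.loci:
        na, fa, _ = _pop_locus(data, pop_a, locus)
        nb, fb, _ = _pop_locus(data, pop_b, locus)
        if na == 0 or nb == 0:
            continue
        hs = 1 - sum(p * p for p in fa.values())
        hs += 1 - sum(p * p for p in fb.values())
        hs /= 2.0
        alleles = set(fa) | set(fb)
        ht = 1 - sum(
            ((fa.get(x, 0.0) + fb.get(x, 0.0)) / 2) ** 2 for x in alleles
        )
        hs_list.append(hs)
        ht_list.append(ht)
    if not hs_list:
        raise ValueError(f"no shared genotyped loci for {pop_a}, {pop_b}")
    HS, HT = float(np.mean(hs_list)), float(np.mean(ht_list))
    gst = (HT - HS) / HT if HT > 0 else 0.0
    comp = GstComponents(HS, HT, gst, 2)
    if HS >= 1.0:
        return comp, np.nan
    gprime = gst * (2 - 1 + HS) / ((2 - 1) * (1 - HS))
    return comp, gprime


def dps(data: GenotypeDataset, pop_a, pop_b) -> float:
    """Shared-allele distance: 1 - mean over loci of sum_a min(p_aA, p_aB).

    Chosen in this field because it avoids mutation-drift equilibrium
    assumptions.
    """
    ps = []
    for locus in data.loci:
        na, fa, _ = _pop_locus(data, pop_a, locus)
        nb, fb, _ = _pop_locus(data, pop_b, locus)
        if na == 0 or nb == 0:
            continue
        ps.append(sum(min(fa.get(x, 0.0), fb.get(x, 0.0))
                      for x in set(fa) | set(fb)))
    if not ps:
        raise ValueError(f"no shared genotyped loci for {pop_a}, {pop_b}")
    return 1.0 - float(np.mean(ps))


def pairwise_genetic_matrix(data: GenotypeDataset, kind="Dps",
                            populations=None) -> PairwiseMatrix:
    """Symmetric site-by-site matrix of FST, GprimeST or Dps."""
    pops = populations or data.populations
    fn = {
        "FST": lambda a, b: fst_wc(data, a, b),
        "GprimeST": lambda a, b: gst_hedrick(data, a, b)[1],
        "Dps": lambda a, b: dps(data, a, b),
    }[kind]
    P = len(pops)
    m = np.zeros((P, P))
    for i, j in itertools.combinations(range(P), 2):
        m[i, j] = m[j, i] = fn(pops[i], pops[j])
    return PairwiseMatrix(list(pops), m, kind)


# -------------------------------------------------------- allelic richness
def allelic_richness(data: GenotypeDataset, g: int):
    """Rarefied allelic richness at ``g`` gene copies.

    ``A_g = sum_a [1 - C(N - N_a, g) / C(N, g)]`` with ``N`` genotyped gene
    copies and ``N_a`` copies of allele ``a``.  Returns a per
    population x locus table and per-population means; entries with
    ``N < g`` are NaN.
    """
    if g < 1:
        raise ValueError("rarefaction size g must be >= 1")

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    rows = []
    for pop in data.populations:
        for locus in data.loci:
            counts = data.allele_counts(pop, locus)
            N = sum(counts.values())
            if N < g or N == 0:
                rows.append((pop, locus, N, np.nan))
                continue
            ag = 0.0
            for na in counts.values():
                if N - na < g:
                    ag += 1.0
                else:
                    ag += 1.0 - np.exp(log_comb(N - na, g) - log_comb(N, g))
            rows.append((pop, locus, N, ag))
    table = pd.DataFrame(rows, columns=["population", "locus", "N", "A_g"])
    means = table.groupby("population", sort=False)["A_g"].mean()
    return table, means


# ------------------------------------------------------------------ AMOVA
@dataclass
class AmovaResult:
    """Three-level AMOVA: among regions / among populations / within."""

    components: dict           # raw variance components
    truncated: dict            # negatives truncated to 0
    percentages: dict          # from truncated components, sum to 100
    phi: dict                  # Phi-statistics
    ss: dict
    df: dict
    truncation_applied: bool = False


def _pair_diffs(counts: np.ndarray) -> float:
    """Number of differing pairs among gene copies with allele counts."""
    m = counts.sum()
    return (m * (m - 1) - (counts * (counts - 1)).sum()) / 2.0


def amova(data: GenotypeDataset, region_map=None) -> AmovaResult:
    """Distance-based AMOVA with allele-identity distance between genes.

    Gene copies carry distance 0 when the alleles match and 1 otherwise
    (an F_ST analogue, not the repeat-size R_ST analogue).  Variance
    components are summed over loci; unequal sample sizes use the standard
    nested-ANOVA coefficients.  Negative components are truncated to zero
    for percentage reporting (flagged), raw values retained.
    """
    ind = data.individuals
    if region_map is not None:
        regions = ind["population"].map(region_map)
    else:
        regions = ind["region"]
    region_of_pop = {}
    for pop, reg in zip(ind["population"], regions):
        region_of_pop.setdefault(pop, reg)
    region_names = sorted(set(region_of_pop.values()), key=str)
    G = len(region_names)
    if G < 1:
        raise ValueError("no regions")
    pops = data.populations
    sig_a = sig_b = sig_c = 0.0
    ss = {"among_regions": 0.0, "among_pops": 0.0, "within_pops": 0.0}
    df = {"among_regions": 0, "among_pops": 0, "within_pops": 0}
    for locus in data.loci:
        # allele count vectors per population
        pop_counts = {}
        for pop in pops:
            c = data.allele_counts(pop, locus)
            if c:
                pop_counts[pop] = np.array(list(c.values()), dtype=float)
        if not pop_counts:
            continue
        by_region = {}
        for pop, counts in pop_counts.items():
            by_region.setdefault(region_of_pop[pop], []).append((pop, counts))
        n_p = {pop: c.sum() for pop, c in pop_counts.items()}
        N = sum(n_p.values())
        P = len(pop_counts)
        Gl = len(by_region)
        ssd_wp = sum(
            _pair_diffs(c) / n_p[pop] for pop, c in pop_counts.items()
        )
        ssd_wr = 0.0
        sum_np2_over_ng = 0.0
        sum_ng2 = 0.0
        all_alleles = {}
        for reg, items in by_region.items():
            merged = {}
            for pop, _ in items:
                for a, cnt in data.allele_counts(pop, locus).items():
                    merged[a] = merged.get(a, 0) + cnt
                    all_alleles[a] = all_alleles.get(a, 0) + cnt
            n_g = sum(merged.values())
            ssd_wr += _pair_diffs(np.array(list(merged.values()),
                                           dtype=float)) / n_g
            sum_np2_over_ng += sum(n_p[pop] ** 2 for pop, _ in items) / n_g
            sum_ng2 += n_g**2
        tot_counts = np.array(list(all_alleles.values()), dtype=float)
        ssd_t = _pair_diffs(tot_counts) / N
        ssd_ap = ssd_wr - ssd_wp
        ssd_ar = ssd_t - ssd_wr
        df_wp = int(N - P)
        df_ap = P - Gl
        df_ar = Gl - 1
        ss["within_pops"] += ssd_wp
        ss["among_pops"] += ssd_ap
        ss["among_regions"] += ssd_ar
        df["within_pops"] += df_wp
        df["among_pops"] += df_ap
        df["among_regions"] += df_ar
        sc = ssd_wp / df_wp if df_wp > 0 else 0.0
        sig_c += sc
        if df_ap > 0:
            n_prime = (N - sum_np2_over_ng) / df_ap
            sb = (ssd_ap / df_ap - sc) / n_prime if n_prime > 0 else 0.0
        else:
            sb = 0.0
        sig_b += sb
        if df_ar > 0:
            sum_np2 = sum(v**2 for v in n_p.values())
            n_dbl = (sum_np2_over_ng - sum_np2 / N) / df_ar
            n_trpl = (N - sum_ng2 / N) / df_ar
            sa = (ssd_ar / df_ar - sc - n_dbl * sb) / n_trpl
        else:
            sa = 0.0
        sig_a += sa
    raw = {"among_regions": sig_a, "among_pops": sig_b,
           "within_pops": sig_c}
    trunc = {k: max(v, 0.0) for k, v in raw.items()}
    total = sum(trunc.values())
    pct = {k: (100.0 * v / total if total > 0 else 0.0)
           for k, v in trunc.items()}
    tot_raw = sum(trunc.values())
    phi = {
        "phi_ct": trunc["among_regions"] / tot_raw if tot_raw else 0.0,
        "phi_sc": (trunc["among_pops"]
                   / (trunc["among_pops"] + trunc["within_pops"])
                   if (trunc["among_pops"] + trunc["within_pops"]) else 0.0),
        "phi_st": ((trunc["among_regions"] + trunc["among_pops"]) / tot_raw
                   if tot_raw else 0.0),
    }
    return AmovaResult(raw, trunc, pct, phi, ss, df,
                       truncation_applied=any(v < 0 for v in raw.values()))


# ------------------------------------------------------- multiple testing
def multiple_test_correction(p_values, method="bonferroni", alpha=0.05):
    """Bonferroni or Hochberg step-up correction.

    Returns a DataFrame with raw p, adjusted p, and reject decisions at
    ``alpha``.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    sm_method = {"bonferroni": "bonferroni",
                 "hochberg": "simes-hochberg"}[method]
    reject, adj, _, _ = multipletests(p, alpha=alpha, method=sm_method)
    return pd.DataFrame({"p": p, "p_adjusted": adj, "reject": reject})
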