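"""Synthetic landscapes and microsatellite genotypes with known truth.

The generator mirrors the data shape of a three-region stream-amphibian
microsatellite study: smooth raster stacks (elevation, canopy, climate,
categorical land cover and stream layers) at a 30 m cell size, and diploid
genotypes at ~9 polymorphic loci for tens of sites with 10-86 individuals
each.  Demes exchange migrants at rates that can be tied to a landscape
resistance matrix, so downstream model selection has a recoverable truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import _coalescent
from .datasets import (
    CATEGORICAL_CODES,
    MISSING,
    GenotypeDataset,
    LandscapeStack,
    PairwiseMatrix,
)

DEFAULT_LAYER_SPECS = {
    "elevation": {"mean": 800.0, "sd": 300.0, "corr_len": 10.0},
    "canopy": {"mean": 60.0, "sd": 20.0, "corr_len": 10.0, "clip": (0.0, 100.0)},
    "frost_free_period": {"mean": 150.0, "sd": 25.0, "corr_len": 10.0,
                          "clip": (0.0, None)},
    "growing_season_precip": {"mean": 250.0, "sd": 60.0, "corr_len": 10.0,
                              "clip": (0.0, None)},
    "heat_load": {"mean": 0.8, "sd": 0.15, "corr_len": 10.0,
                  "clip": (0.0, None)},
    "land_cover": {"corr_len": 6.0, "proportions": {1: 0.7, 2: 0.2, 3: 0.1}},
    "stream": {"corr_len": 3.0, "proportions": {1: 0.1, 2: 0.9}},
}


def _random_field(shape, corr_len, rng):
    """Stationary Gaussian field, zero mean / unit variance, via filtering."""
    z = rng.standard_normal(shape)
    if corr_len > 0:
        z = ndimage.gaussian_filter(z, sigma=corr_len, mode="reflect")
        sd = z.std()
        if sd > 0:
            z = (z - z.mean()) / sd
    return z


def generate_landscape(n_rows, n_cols, cell_size=30.0, layer_specs=None,
                       seed=None) -> LandscapeStack:
    """Generate a co-registered raster stack with controlled smoothness.

    Continuous layers are Gaussian random fields rescaled to the requested
    mean/sd (``sd = 0`` gives a constant layer); ``corr_len`` is the
    Gaussian-filter length in cells.  Categorical layers are obtained by
    thresholding an auxiliary field at the quantiles implied by the
    requested category proportions.  Slope (degrees) is derived from
    elevation by central finite differences.  Identical seeds give
    identical stacks.
    """
    specs = {k: dict(v) for k, v in DEFAULT_LAYER_SPECS.items()}
    for name, spec in (layer_specs or {}).items():
        if name not in specs:
            raise ValueError(f"unknown layer {name!r}; "
                             f"known: {sorted(specs)}")
        specs[name].update(spec)
    rng = np.random.default_rng(seed)
    layers = {}
    for name in sorted(specs):  # fixed order => deterministic streams
        spec = specs[name]
        if "proportions" in spec:
            props = spec["proportions"]
            codes = sorted(props)
            if set(codes) - set(CATEGORICAL_CODES[name]):
                raise ValueError(f"bad codes for {name}: {codes}")
            z = _random_field((n_rows, n_cols), spec["corr_len"], rng)
            cum = np.cumsum([props[c] for c in codes])
            cum = cum / cum[-1]
            cuts = np.quantile(z, cum[:-1])
            idx = np.digitize(z, cuts, right=True)
            layers[name] = np.array(codes, dtype=float)[idx]
        else:
            sd = float(spec.get("sd", 0.0))
            if sd < 0:
                raise ValueError(f"negative variance for {name}")
            if sd == 0:
                grid = np.full((n_rows, n_cols), float(spec["mean"]))
                rng.standard_normal((n_rows, n_cols))  # keep stream aligned
            else:
                z = _random_field((n_rows, n_cols), spec["corr_len"], rng)
                grid = spec["mean"] + sd * z
            lo, hi = spec.get("clip", (None, None))
            grid = np.clip(grid, lo, hi)
            layers[name] = grid
    layers["slope"] = slope_from_elevation(layers["elevation"], cell_size)
    return LandscapeStack(n_rows, n_cols, cell_size, layers)


def slope_from_elevation(elevation, cell_size) -> np.ndarray:
    """Slope in degrees from central finite differences of elevation."""
    gy, gx = np.gradient(np.asarray(elevation, dtype=float), cell_size)
    return np.degrees(np.arctan(np.hypot(gx, gy)))


# ---------------------------------------------------------------- migration
def migration_from_resistance(resistance, m0, alpha) -> np.ndarray:
    """Row-stochastic migration matrix with rates decaying in resistance.

    ``m_ij = m0 * exp(-alpha * R_ij) / (D - 1)`` off the diagonal, diagonal
    set to the remainder, so total emigration per row is at most ``m0`` and
    every off-diagonal rate is non-increasing in ``alpha``.
    """
    R = resistance.values if isinstance(resistance, PairwiseMatrix) else \
        np.asarray(resistance, dtype=float)
    if not np.allclose(R, R.T, atol=1e-9):
        raise ValueError("resistance matrix must be symmetric")
    if (R < 0).any():
        raise ValueError("resistance must be non-negative")
    if not 0 < m0 < 1:
        raise ValueError("m0 must be in (0, 1)")
    D = R.shape[0]
    M = m0 * np.exp(-alpha * R) / (D - 1)
    np.fill_diagonal(M, 0.0)
    np.fill_diagonal(M, 1.0 - M.sum(axis=1))
    return M


# -------------------------------------------------------------- forward sim
@dataclass
class SimParams:
    """Forward Wright-Fisher metapopulation parameters.

    ``deme_sizes`` are diploid individuals per deme; ``migration`` is the
    row-stochastic backward matrix (row d = source-deme distribution of an
    offspring born in d); ``mu`` the per-locus per-generation mutation
    rate; ``burn_in`` the number of generations simulated (guidance: at
    least 10x the largest deme size to approach mutation-drift
    equilibrium).
    """

    n_demes: int
    deme_sizes: np.ndarray
    migration: np.ndarray
    mu: float
    n_loci: int = 9
    allele_bounds: tuple = (5, 60)
    burn_in: int = None
    sample_sizes: np.ndarray = None
    missing_rate: float = 0.0

    def __post_init__(self):
        self.deme_sizes = np.broadcast_to(
            np.asarray(self.deme_sizes, dtype=int), (self.n_demes,)
        ).copy()
        self.migration = np.asarray(self.migration, dtype=float)
        if self.migration.shape != (self.n_demes, self.n_demes):
            raise ValueError(
                f"migration shape {self.migration.shape} does not match "
                f"{self.n_demes} demes"
            )
        if not np.allclose(self.migration.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("migration rows must sum to 1")
        if not 0 < self.mu < 1:
            raise ValueError("mu must be in (0, 1)")
        if (self.deme_sizes < 2).any():
            raise ValueError("deme sizes must be >= 2")
        if self.burn_in is None:
            self.burn_in = 10 * int(self.deme_sizes.max())
        if self.sample_sizes is None:
            self.sample_sizes = self.deme_sizes.copy()
        self.sample_sizes = np.minimum(
            np.broadcast_to(np.asarray(self.sample_sizes, dtype=int),
                            (self.n_demes,)),
            self.deme_sizes,
        )


def _reflect(vals, lo, hi):
    vals = np.where(vals < lo, 2 * lo - vals, vals)
    return np.where(vals > hi, 2 * hi - vals, vals)


def simulate_metapopulation(params: SimParams, seed=None,
                            pop_labels=None, region_labels=None
                            ) -> GenotypeDataset:
    """Forward-in-time Wright-Fisher simulation with migration and SMM.

    Each generation every offspring draws a source deme from its deme's
    migration row, two uniform parents from that deme, one allele per
    parent, then mutates each allele with probability ``mu`` by +-1 repeat,
    reflecting at ``allele_bounds``.  Returns a per-deme sample as a
    :class:`GenotypeDataset`.
    """
    rng = np.random.default_rng(seed)
    D, L = params.n_demes, params.n_loci
    lo, hi = params.allele_bounds
    sizes = params.deme_sizes
    N = int(sizes.max())
    mid = (lo + hi) // 2
    pop = np.full((D, N, L, 2), mid, dtype=np.int16)
    cum = np.cumsum(params.migration, axis=1)
    alive = np.arange(N)[None, :] < sizes[:, None]  # (D, N)
    deme_of = np.repeat(np.arange(D), sizes)
    n_off = int(sizes.sum())
    cum_off = cum[deme_of]  # (n_off, D)

    for _ in range(params.burn_in):
        u = rng.random(n_off)
        src = (u[:, None] > cum_off).sum(axis=1)
        p1 = (rng.random(n_off) * sizes[src]).astype(np.int64)
        p2 = (rng.random(n_off) * sizes[src]).astype(np.int64)
        a1 = rng.integers(0, 2, size=(n_off, L, 1))
        a2 = rng.integers(0, 2, size=(n_off, L, 1))
        g1 = np.take_along_axis(pop[src, p1], a1, axis=2)[..., 0]
        g2 = np.take_along_axis(pop[src, p2], a2, axis=2)[..., 0]
        children = np.stack([g1, g2], axis=2)
        mut = rng.random(children.shape) < params.mu
        nm = int(mut.sum())
        if nm:
            steps = 2 * rng.integers(0, 2, size=nm) - 1
            children = children.astype(np.int32)
            children[mut] += steps
            children = _reflect(children, lo, hi).astype(np.int16)
        new = np.full_like(pop, mid)
        new[alive] = children
        pop = new

    # sample per deme
    labels = pop_labels or [f"deme{d + 1}" for d in range(D)]
    regions = region_labels or ["all"] * D
    rows, calls = [], []
    for d in range(D):
        k = int(params.sample_sizes[d])
        pick = rng.choice(sizes[d], size=k, replace=False)
        for j, ind in enumerate(pick):
            rows.append((f"{labels[d]}_i{j + 1}", labels[d], regions[d]))
            calls.append(pop[d, ind].astype(np.int64))
    calls = np.array(calls)
    if params.missing_rate > 0:
        drop = rng.random(calls.shape[:2]) < params.missing_rate
        calls[drop] = MISSING
    individuals = pd.DataFrame(rows, columns=["id", "population", "region"])
    return GenotypeDataset(individuals, [f"L{j + 1}" for j in range(L)], calls)


# ---------------------------------------------------------- coalescent sim
def simulate_size_change_sample(N0, N1, Ta, mu, n, n_loci, seed=None,
                                allele_bounds=(5, 60), population="pop1",
                                region="all") -> GenotypeDataset:
    """Sample ``n`` diploids from a population with exponential size change.

    Backward in time the diploid effective size follows
    ``N(t) = N0 * (N1/N0)**(t/Ta)`` for ``t`` in ``[0, Ta]`` and ``N1``
    earlier; genealogies of ``2n`` genes per locus receive Poisson
    single-step mutations (rate ``mu`` per generation per lineage), rooted
    at the midpoint of ``allele_bounds`` and reflected into the bounds.
    """
    if min(N0, N1, mu) <= 0 or Ta < 0 or n < 2 or n_loci < 1:
        raise ValueError("parameters must be positive (Ta may be 0)")
    rng = np.random.default_rng(seed)
    lo, hi = allele_bounds
    durations = _coalescent.size_change_durations(
        2 * n, N0, N1, Ta, rng, size=n_loci
    )
    alleles = _coalescent.drop_mutations_smm(
        durations, mu, rng, root=(lo + hi) // 2
    )
    # fold unbounded walk into the allowed repeat range
    period = 2 * (hi - lo)
    x = np.mod(alleles - lo, period)
    alleles = lo + np.minimum(x, period - x)
    calls = alleles.reshape(n_loci, n, 2).transpose(1, 0, 2)
    individuals = pd.DataFrame(
        {"id": [f"{population}_i{j + 1}" for j in range(n)],
         "population": population, "region": region}
    )
    return GenotypeDataset(
        individuals, [f"L{j + 1}" for j in range(n_loci)], calls
    )
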