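"""Core in-memory containers shared across the package.

Microsatellite genotypes are held as an integer call array (repeat sizes,
missing coded as :data:`MISSING`) alongside a pandas table of individual
metadata; landscape layers are held as a dict of co-registered numpy grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing allele call.
MISSING = -1

#: Allowed codes for categorical landscape layers.
CATEGORICAL_CODES = {"land_cover": (1, 2, 3), "stream": (1, 2)}

#: Continuous layers of the standard variable roster.
CONTINUOUS_LAYERS = (
    "elevation",
    "slope",
    "canopy",
    "frost_free_period",
    "growing_season_precip",
    "heat_load",
)


@dataclass
class GenotypeDataset:
    """Diploid microsatellite calls with population and region labels.

    Parameters
    ----------
    individuals : pandas.DataFrame
        One row per individual with columns ``id``, ``population`` and
        (optionally) ``region``.
    loci : list of str
        Locus names, in call-array column order.
    calls : ndarray of shape (n_individuals, n_loci, 2)
        Integer allele repeat sizes; :data:`MISSING` marks missing calls.
        A genotype is treated as missing if either allele is missing.
    """

    individuals: pd.DataFrame
    loci: list
    calls: np.ndarray

    def __post_init__(self):
        self.individuals = self.individuals.reset_index(drop=True)
        if "region" not in self.individuals.columns:
            self.individuals = self.individuals.assign(region="all")
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n = len(self.individuals)
        if self.calls.shape != (n, len(self.loci), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{n} individuals x {len(self.loci)} loci x 2"
            )

    # -- basic views -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def populations(self) -> list:
        return list(pd.unique(self.individuals["population"]))

    @property
    def regions(self) -> list:
        return list(pd.unique(self.individuals["region"]))

    def locus_index(self, locus) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci) mask of missing genotypes."""
        return (self.calls == MISSING).any(axis=2)

    def subset(self, mask=None, populations=None) -> "GenotypeDataset":
        """Subset by boolean mask over individuals or by population labels."""
        if populations is not None:
            mask = self.individuals["population"].isin(populations).to_numpy()
        mask = np.asarray(mask, dtype=bool)
        return GenotypeDataset(
            self.individuals[mask], list(self.loci), self.calls[mask]
        )

    def genotypes(self, population, locus) -> np.ndarray:
        """Non-missing genotype rows (n, 2) for one population x locus."""
        li = self.locus_index(locus)
        rows = (self.individuals["population"] == population).to_numpy()
        g = self.calls[rows, li, :]
        return g[(g != MISSING).all(axis=1)]

    def allele_counts(self, population, locus) -> dict:
        """Allele -> count of gene copies among genotyped individuals."""
        g = self.genotypes(population, locus)
        alleles, counts = np.unique(g.ravel(), return_counts=True)
        return dict(zip(alleles.tolist(), counts.tolist()))

    def merged_population(self, label="pooled") -> "GenotypeDataset":
        ind = self.individuals.assign(population=label)
        return GenotypeDataset(ind, list(self.loci), self.calls)


@dataclass
class LandscapeStack:
    """Co-registered raster layers on a common grid.

    Continuous layers (elevation m, canopy %, frost_free_period days,
    growing_season_precip mm, heat_load index, derived slope degrees) and
    categorical layers (land_cover codes 1=forest, 2=non-forest natural,
    3=barrier; stream codes 1=stream, 2=other) share dimensions, the cell
    size (metres) and a nodata mask.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    layers: dict = field(default_factory=dict)
    nodata_mask: np.ndarray = None
    xllcorner: float = 0.0
    yllcorner: float = 0.0

    def __post_init__(self):
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid dimensions must be at least 2x2")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros((self.n_rows, self.n_cols), dtype=bool)
        self.validate()

    def validate(self):
        shape = (self.n_rows, self.n_cols)
        if self.nodata_mask.shape != shape:
            raise ValueError("nodata_mask shape mismatch")
        for name, grid in self.layers.items():
            if grid.shape != shape:
                raise ValueError(f"layer {name!r} shape {grid.shape} != {shape}")
            if name in CATEGORICAL_CODES:
                valid = np.isin(grid[~self.nodata_mask], CATEGORICAL_CODES[name])
                if not valid.all():
                    raise ValueError(f"layer {name!r} has codes outside "
                                     f"{CATEGORICAL_CODES[name]}")
        if "slope" in self.layers:
            slope = self.layers["slope"][~self.nodata_mask]
            if (slope < 0).any():
                raise ValueError("slope must be non-negative")

    def __getitem__(self, name):
        return self.layers[name]


@dataclass
class SiteTable:
    """Sampling sites: id, projected x/y coordinates (metres), region."""

    table: pd.DataFrame  # columns: site, x, y, region

    def __post_init__(self):
        t = self.table.reset_index(drop=True)
        if t["site"].duplicated().any():
            raise ValueError("duplicate site ids")
        xy = t[["x", "y"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            raise ValueError("non-finite site coordinates")
        # Heuristic guard: buffer arithmetic needs projected metres.
        if (np.abs(xy[:, 0]) <= 180).all() and (np.abs(xy[:, 1]) <= 90).all():
            raise ValueError(
                "site coordinates look geographic (degrees); project them to "
                "metres before use"
            )
        self.table = t

    @property
    def sites(self) -> list:
        return list(self.table["site"])


@dataclass
class PairwiseMatrix:
    """Symmetric site-by-site matrix (genetic distance or resistance)."""

    ids: list
    values: np.ndarray
    kind: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-9, equal_nan=True):
            raise ValueError("matrix is not symmetric")
        self.values = (v + v.T) / 2.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def reorder(self, ids) -> "PairwiseMatrix":
        idx = [self.ids.index(i) for i in ids]
        return PairwiseMatrix(
            list(ids), self.values[np.ix_(idx, idx)], self.kind,
            dict(self.provenance),
        )
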