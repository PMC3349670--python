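"""Landscape resistance surfaces and circuit-theory effective resistance.

Raster layers become resistance surfaces (linear rescaling for continuous
variables in the hypothesised direction; cost tables for categorical
ones), the non-nodata cells of a surface become a 4-neighbour lattice
whose edge resistances average the two adjacent cell resistances, and
pairwise effective resistance between focal sites is obtained from sparse
grounded-Laplacian solves.  A flat all-ones surface gives the
isolation-by-resistance (IBR) baseline, the circuit analogue of isolation
by distance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import csgraph
from scipy.sparse.linalg import splu

from .datasets import LandscapeStack, PairwiseMatrix, SiteTable

#: Cost tables for the two alternative parameterizations per categorical
#: variable: land cover 1(forest):2(non-forest natural):3(barrier) and
#: stream 1(stream):2(other).
COST_TABLES = {
    "LC10": {1: 1.0, 2: 5.0, 3: 10.0},
    "LC100": {1: 1.0, 2: 50.0, 3: 100.0},
    "STR10": {1: 1.0, 2: 10.0},
    "STR100": {1: 1.0, 2: 100.0},
}

#: Hypothesised direction of dispersal resistance for continuous layers:
#: '+' resistance grows with the value, '-' it shrinks.
CONTINUOUS_DIRECTIONS = {
    "elevation": ("ELEV", "+"),
    "slope": ("SLP", "+"),
    "canopy": ("CAN", "-"),
    "frost_free_period": ("FFP", "-"),
    "heat_load": ("HLI", "+"),
    "growing_season_precip": ("GSP", "-"),
}


@dataclass
class ResistanceSurface:
    """Per-cell dimensionless resistance >= r_min with provenance."""

    values: np.ndarray
    cell_size: float
    nodata_mask: np.ndarray = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        if (self.values[~self.nodata_mask] <= 0).any():
            raise ValueError("resistance values must be positive")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class FocalSites:
    """Site ids mapped to raster cell indices (one focal cell per site)."""

    ids: list
    rows: np.ndarray
    cols: np.ndarray
    xy: np.ndarray = None

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=int)
        self.cols = np.asarray(self.cols, dtype=int)
        cells = list(zip(self.rows.tolist(), self.cols.tolist()))
        if len(set(cells)) != len(cells):
            raise ValueError("two sites fall in the same raster cell")


def locate_sites(sites: SiteTable, shape, cell_size, xllcorner=0.0,
                 yllcorner=0.0) -> FocalSites:
    """Map site coordinates to the raster cell containing each site.

    Row 0 is the northern edge (ESRI ASCII convention).
    """
    n_rows, n_cols = shape
    t = sites.table
    cols = np.floor((t["x"].to_numpy() - xllcorner) / cell_size).astype(int)
    rows_from_bottom = np.floor(
        (t["y"].to_numpy() - yllcorner) / cell_size
    ).astype(int)
    rows = n_rows - 1 - rows_from_bottom
    bad = (rows < 0) | (rows >= n_rows) | (cols < 0) | (cols >= n_cols)
    if bad.any():
        raise ValueError(
            f"sites outside grid: {list(t.loc[bad, 'site'])}"
        )
    return FocalSites(list(t["site"]), rows, cols,
                      t[["x", "y"]].to_numpy(dtype=float))


# ------------------------------------------------------------ conversions
def continuous_to_resistance(layer, direction="+", r_min=1.0, r_max=10.0,
                             cell_size=30.0, nodata_mask=None,
                             name="") -> ResistanceSurface:
    """Linear min-max rescale of a continuous layer to [r_min, r_max].

    ``direction='-'`` inverts the ordering (layer maximum maps to r_min).
    A constant layer maps everywhere to r_min, with a warning.
    """
    if r_max <= r_min:
        raise ValueError("r_max must exceed r_min")
    if direction not in ("+", "-"):
        raise ValueError("direction must be '+' or '-'")
    layer = np.asarray(layer, dtype=float)
    mask = np.zeros(layer.shape, bool) if nodata_mask is None else nodata_mask
    vals = layer[~mask]
    if vals.size == 0:
        raise ValueError("layer has no data cells")
    lo, hi = vals.min(), vals.max()
    out = np.full(layer.shape, r_min, dtype=float)
    if hi == lo:
        warnings.warn(f"constant layer {name!r}: resistance set to r_min")
    else:
        scaled = (layer - lo) / (hi - lo)
        if direction == "-":
            scaled = 1.0 - scaled
        out = r_min + scaled * (r_max - r_min)
        out[mask] = r_min
    return ResistanceSurface(
        out, cell_size, mask,
        {"variable": name, "direction": direction,
         "r_min": r_min, "r_max": r_max},
    )


def categorical_to_resistance(layer, cost_table, cell_size=30.0,
                              nodata_mask=None, name="") -> ResistanceSurface:
    """Map categorical codes to resistances through a cost table."""
    layer = np.asarray(layer)
    mask = np.zeros(layer.shape, bool) if nodata_mask is None else nodata_mask
    codes = np.unique(layer[~mask])
    missing = [c for c in codes.tolist() if c not in cost_table]
    if missing:
        counts = {c: int((layer[~mask] == c).sum()) for c in missing}
        raise ValueError(f"codes without costs: {counts} (code: cell count)")
    out = np.ones(layer.shape, dtype=float)
    for code, cost in cost_table.items():
        out[layer == code] = cost
    return ResistanceSurface(out, cell_size, mask,
                             {"variable": name, "cost_table": dict(cost_table)})


def ibr_surface(dims, cell_size=30.0) -> ResistanceSurface:
    """Flat landscape, all cells 1: the isolation-by-resistance baseline."""
    n_rows, n_cols = dims
    if n_rows < 2 or n_cols < 2:
        raise ValueError("dims must be at least 2x2")
    return ResistanceSurface(np.ones((n_rows, n_cols)), cell_size,
                             provenance={"variable": "IBR"})


def candidate_surfaces(stack: LandscapeStack) -> dict:
    """Full named candidate roster from a landscape stack.

    Continuous variables use their hypothesised resistance direction;
    categorical variables contribute two alternative cost-ratio
    parameterizations each; the flat IBR baseline is always included.
    """
    out = {"IBR": ibr_surface((stack.n_rows, stack.n_cols), stack.cell_size)}
    for layer, (code, direction) in CONTINUOUS_DIRECTIONS.items():
        if layer in stack.layers:
            out[code] = continuous_to_resistance(
                stack[layer], direction, cell_size=stack.cell_size,
                nodata_mask=stack.nodata_mask, name=code,
            )
    pairs = {"land_cover": ("LC10", "LC100"), "stream": ("STR10", "STR100")}
    for layer, names in pairs.items():
        if layer in stack.layers:
            for nm in names:
                out[nm] = categorical_to_resistance(
                    stack[layer], COST_TABLES[nm], cell_size=stack.cell_size,
                    nodata_mask=stack.nodata_mask, name=nm,
                )
    return out


# ------------------------------------------------------------------- clip
def clip_buffer(obj, sites: FocalSites, buffer_m=500.0):
    """Crop to the site bounding box plus a buffer, re-mapping site cells.

    The buffer is ``ceil(buffer_m / cell_size)`` cells per side, clamped to
    the grid; the default 500 m at 30 m cells expands by 17 cells.
    Returns ``(clipped_object, remapped_sites)``.
    """
    if isinstance(obj, LandscapeStack):
        shape, cell = (obj.n_rows, obj.n_cols), obj.cell_size
    else:
        shape, cell = obj.shape, obj.cell_size
    pad = math.ceil(buffer_m / cell)
    r0 = max(int(sites.rows.min()) - pad, 0)
    r1 = min(int(sites.rows.max()) + pad + 1, shape[0])
    c0 = max(int(sites.cols.min()) - pad, 0)
    c1 = min(int(sites.cols.max()) + pad + 1, shape[1])
    new_sites = FocalSites(list(sites.ids), sites.rows - r0, sites.cols - c0,
                           sites.xy)
    if isinstance(obj, LandscapeStack):
        clipped = LandscapeStack(
            r1 - r0, c1 - c0, obj.cell_size,
            {k: v[r0:r1, c0:c1] for k, v in obj.layers.items()},
            obj.nodata_mask[r0:r1, c0:c1],
        )
    else:
        clipped = ResistanceSurface(
            obj.values[r0:r1, c0:c1], obj.cell_size,
            obj.nodata_mask[r0:r1, c0:c1], dict(obj.provenance),
        )
    return clipped, new_sites


# ------------------------------------------------- effective resistance
def _lattice_laplacian(surface: ResistanceSurface):
    """Sparse Laplacian of the 4-neighbour lattice on data cells.

    Edge resistance between adjacent cells is the arithmetic mean of the
    two cell resistances; conductance is its reciprocal.  Returns
    (laplacian, node_index_grid).
    """
    R = surface.values
    ok = ~surface.nodata_mask
    idx = -np.ones(R.shape, dtype=np.int64)
    idx[ok] = np.arange(int(ok.sum()))
    rows, cols, conds = [], [], []
    for dr, dc in ((0, 1), (1, 0)):
        a_ok = ok[: R.shape[0] - dr, : R.shape[1] - dc]
        b_ok = ok[dr:, dc:]
        both = a_ok & b_ok
        ra = R[: R.shape[0] - dr, : R.shape[1] - dc][both]
        rb = R[dr:, dc:][both]
        ia = idx[: R.shape[0] - dr, : R.shape[1] - dc][both]
        ib = idx[dr:, dc:][both]
        g = 2.0 / (ra + rb)
        rows.append(ia)
        cols.append(ib)
        conds.append(g)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    conds = np.concatenate(conds)
    n = int(ok.sum())
    A = sparse.coo_matrix(
        (np.concatenate([conds, conds]),
         (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(n, n),
    ).tocsr()
    L = sparse.diags(np.asarray(A.sum(axis=1)).ravel()) - A
    return L.tocsc(), idx


def effective_resistance(surface: ResistanceSurface,
                         sites: FocalSites) -> PairwiseMatrix:
    """Pairwise effective resistance between focal sites.

    Nodata cells are removed from the graph (infinite resistance).  The
    focal cells must lie in one connected component; otherwise the error
    names the components.  Solved by grounding one focal node and sparse
    LU solves of the reduced Laplacian, one right-hand side per focal
    node.
    """
    L, idx = _lattice_laplacian(surface)
    focal = idx[sites.rows, sites.cols]
    if (focal < 0).any():
        bad = [s for s, f in zip(sites.ids, focal) if f < 0]
        raise ValueError(f"focal sites on nodata cells: {bad}")
    n_comp, labels = csgraph.connected_components(
        sparse.csr_matrix((L != 0).astype(np.int8)), directed=False
    )
    comp = labels[focal]
    if len(set(comp.tolist())) > 1:
        groups = {}
        for s, c in zip(sites.ids, comp.tolist()):
            groups.setdefault(c, []).append(s)
        raise ValueError(
            f"focal sites span disconnected components: {groups}"
        )
    ground = focal[0]
    keep = np.ones(L.shape[0], dtype=bool)
    keep[ground] = False
    Lg = L[keep][:, keep].tocsc()
    remap = np.cumsum(keep) - 1  # old index -> reduced index
    lu = splu(Lg)
    S = len(sites.ids)
    pots = np.zeros((S, L.shape[0]))  # potentials for unit injection at f
    for si in range(1, S):
        b = np.zeros(Lg.shape[0])
        b[remap[focal[si]]] = 1.0
        x = lu.solve(b)
        pots[si, keep] = x
    m = np.zeros((S, S))
    for i in range(S):
        for j in range(i + 1, S):
            rij = (pots[i, focal[i]] + pots[j, focal[j]]
                   - pots[i, focal[j]] - pots[j, focal[i]])
            m[i, j] = m[j, i] = rij
    return PairwiseMatrix(
        list(sites.ids), m, "resistance",
        {"surface": surface.provenance.get("variable", "?")},
    )


# ------------------------------------------------------- multivariate sum
def standardize_and_sum(surfaces) -> ResistanceSurface:
    """Min-max rescale each surface to [1, 10] cellwise and sum them.

    Constant surfaces map to 1 everywhere (with a warning).  All surfaces
    must be co-registered.
    """
    surfaces = list(surfaces)
    if not surfaces:
        raise ValueError("no surfaces")
    shape = surfaces[0].shape
    mask = np.zeros(shape, dtype=bool)
    for s in surfaces:
        if s.shape != shape:
            raise ValueError("surfaces are not co-registered")
        mask |= s.nodata_mask
    total = np.zeros(shape)
    names = []
    for s in surfaces:
        v = s.values
        lo, hi = v[~mask].min(), v[~mask].max()
        if hi == lo:
            warnings.warn("constant surface in multivariate sum: mapped to 1")
            scaled = np.ones(shape)
        else:
            scaled = 1.0 + 9.0 * (v - lo) / (hi - lo)
        total += scaled
        names.append(s.provenance.get("variable", "?"))
    total[mask] = 1.0
    return ResistanceSurface(
        total, surfaces[0].cell_size, mask,
        {"variable": "+".join(names), "combination": "standardized_sum"},
    )


def resistance_matrices(surfaces: dict, sites: FocalSites) -> dict:
    """Effective-resistance matrix for each named surface."""
    return {name: effective_resistance(s, sites)
            for name, s in surfaces.items()}
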