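"""File formats: GenePop genotype files, ESRI ASCII grids, site tables.

GenePop is the de-facto exchange format for microsatellite data: a title
line, one locus name per line (or a comma-separated line), then ``POP``
blocks of ``individual_id ,  aaabbb aaabbb ...`` rows where each token is a
2- or 3-digit-per-allele diploid genotype and all-zero alleles mean missing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import MISSING, GenotypeDataset, SiteTable


# ---------------------------------------------------------------- GenePop
def write_genepop(data: GenotypeDataset, path, title="streamscape export",
                  digits=3):
    """Write a :class:`GenotypeDataset` as a GenePop file.

    Alleles are written with ``digits`` digits each; missing calls as zeros
    (``000000`` for 3-digit files).
    """
    lines = [title]
    lines.extend(str(locus) for locus in data.loci)
    fmt = f"0{digits}d"
    for pop in data.populations:
        lines.append("POP")
        sub = data.individuals["population"] == pop
        for row, ind_id in zip(
            data.calls[sub.to_numpy()], data.individuals.loc[sub, "id"]
        ):
            toks = []
            for a, b in row:
                if a == MISSING or b == MISSING:
                    toks.append("0" * (2 * digits))
                else:
                    toks.append(f"{a:{fmt}}{b:{fmt}}")
            lines.append(f"{ind_id} ,  " + " ".join(toks))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genepop(path, region_map=None) -> GenotypeDataset:
    """Read a GenePop file.

    Population labels are ``pop1`` ... ``popK`` in file order; pass
    ``region_map`` (population -> region) to attach region labels.
    Raises ``ValueError`` with a line number for ragged rows or mixed
    allele widths.
    """
    raw = Path(path).read_text().splitlines()
    lines = [ln for ln in raw]
    if len(lines) < 3:
        raise ValueError("not a GenePop file: fewer than 3 lines")
    # locus names: either one per line until first POP, possibly one
    # comma-separated line
    loci = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        part = lines[i].strip()
        if part:
            loci.extend(x.strip() for x in part.split(",") if x.strip())
        i += 1
    if not loci:
        raise ValueError("no locus names found")
    records = []
    calls = []
    pop_idx = 0
    width = None
    while i < len(lines):
        line = lines[i].strip()
        if line.upper() == "POP":
            pop_idx += 1
            i += 1
            continue
        if not line:
            i += 1
            continue
        if "," not in line:
            raise ValueError(f"line {i + 1}: expected 'id , genotypes'")
        ind_id, geno = line.split(",", 1)
        toks = geno.split()
        if len(toks) != len(loci):
            raise ValueError(
                f"line {i + 1}: {len(toks)} genotypes for {len(loci)} loci"
            )
        row = np.empty((len(loci), 2), dtype=np.int64)
        for j, tok in enumerate(toks):
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise ValueError(f"line {i + 1}: bad genotype token {tok!r}")
            w = len(tok) // 2
            if width is None:
                width = w
            elif w != width:
                raise ValueError(
                    f"line {i + 1}: allele width {w} mixed with {width}"
                )
            a, b = int(tok[:w]), int(tok[w:])
            row[j] = (a if a else MISSING, b if b else MISSING)
        records.append((ind_id.strip(), f"pop{pop_idx}"))
        calls.append(row)
        i += 1
    individuals = pd.DataFrame(records, columns=["id", "population"])
    if region_map is not None:
        individuals["region"] = individuals["population"].map(region_map)
    return GenotypeDataset(individuals, loci, np.array(calls))


# ---------------------------------------------------------- ESRI ASCII grid
_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value")


def write_ascii_grid(grid, path, cell_size=30.0, xllcorner=0.0,
                     yllcorner=0.0, nodata_value=-9999.0, mask=None):
    """Write a 2-D array as an ESRI ASCII grid (row 0 = northern edge)."""
    grid = np.asarray(grid, dtype=float)
    out = grid.copy()
    if mask is not None:
        out[mask] = nodata_value
    nrows, ncols = grid.shape
    header = (
        f"NCOLS {ncols}\nNROWS {nrows}\n"
        f"XLLCORNER {xllcorner:.6f}\nYLLCORNER {yllcorner:.6f}\n"
        f"CELLSIZE {cell_size:.6f}\nNODATA_VALUE {nodata_value:.6f}\n"
    )
    body = "\n".join(" ".join(f"{v:.6g}" for v in row) for row in out)
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path):
    """Read an ESRI ASCII grid.

    Returns ``(grid, mask, header)`` where ``mask`` flags nodata cells and
    ``header`` is a dict with the six standard keys (lower-cased).
    """
    lines = Path(path).read_text().splitlines()
    header = {}
    i = 0
    while i < len(lines) and len(header) < 6:
        key, _, value = lines[i].partition(" ")
        key = key.strip().lower()
        if key not in _HEADER_KEYS:
            raise ValueError(f"unexpected header line {i + 1}: {lines[i]!r}")
        header[key] = float(value)
        i += 1
    if set(header) != set(_HEADER_KEYS):
        raise ValueError(f"incomplete header: {sorted(header)}")
    body = np.array(
        [row.split() for row in lines[i:] if row.strip()], dtype=float
    ) if any(ln.strip() for ln in lines[i:]) else np.empty((0, 0))
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if body.shape != (nrows, ncols):
        raise ValueError(
            f"body shape {body.shape} does not match header "
            f"({nrows}, {ncols})"
        )
    mask = np.isclose(body, header["nodata_value"])
    return body, mask, header


# -------------------------------------------------------------- site table
def read_site_table(path) -> SiteTable:
    """Read a delimited site table with columns site, x, y[, region]."""
    t = pd.read_csv(path, comment="#")
    required = {"site", "x", "y"}
    if not required.issubset(t.columns):
        raise ValueError(f"site table needs columns {sorted(required)}")
    if "region" not in t.columns:
        t["region"] = "all"
    return SiteTable(t)


# ------------------------------------------------------------------ filters
def apply_missingness_filter(data: GenotypeDataset, max_missing_loci=2):
    """Drop individuals with missing genotypes at more loci than allowed.

    With the default ``max_missing_loci=2``, an individual missing data at
    three or more loci is excluded.  Returns the filtered dataset and a
    per-population report of dropped counts.
    """
    n_missing = data.missing_mask().sum(axis=1)
    keep = n_missing <= max_missing_loci
    dropped = data.individuals.loc[~keep, "population"]
    report = (
        dropped.value_counts().rename("n_dropped").rename_axis("population")
        .reset_index()
    )
    return data.subset(mask=keep), report


def drop_duplicate_genotypes(data: GenotypeDataset):
    """Keep one individual per exact multilocus genotype within population.

    A deliberately simple stand-in for sibship-based pruning: full sibs
    often share genotypes at few loci, but only exact duplicates are
    removed here.
    """
    flat = data.calls.reshape(data.n_individuals, -1)
    key = pd.DataFrame(flat)
    key["population"] = data.individuals["population"].to_numpy()
    keep = ~key.duplicated().to_numpy()
    return data.subset(mask=keep)


def write_table(df: pd.DataFrame, path, provenance=None):
    """Write a delimited report table with '#' provenance header lines."""
    path = Path(path)
    with path.open("w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)
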