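"""End-to-end driver: simulate -> stats -> resistance -> regress -> demography.

Each stage derives its own seed from one global seed, logs its parameters,
and writes delimited report tables with provenance headers, so a full run
is reproducible from the config alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bottleneck as bn
from . import demography as dem
from . import io as sio
from . import model_selection as ms
from . import popgen, resistance, synthetic
from ._random import derive_seed

log = logging.getLogger("streamscape")

ALL_STAGES = ("simulate", "stats", "bottleneck", "resistance", "regress",
              "demography")


@dataclass
class RunConfig:
    """Pipeline configuration; every stage seed derives from ``seed``."""

    out_dir: str = "streamscape_run"
    seed: int = 0
    stages: tuple = ALL_STAGES
    # synthetic stage
    n_rows: int = 40
    n_cols: int = 40
    cell_size: float = 30.0
    n_demes: int = 8
    deme_size: int = 80
    sample_size: int = 20
    n_loci: int = 9
    mu: float = 5e-3
    burn_in: int = 600
    m0: float = 0.2
    alpha: float = 0.5
    truth_variable: str = "ELEV"
    n_regions: int = 2
    # analysis parameters
    rarefaction_g: int = 20
    alpha_level: float = 0.05
    buffer_m: float = 500.0
    ri_threshold: float = 0.60
    distance_measure: str = "Dps"
    bottleneck_reps: int = 2000
    bottleneck_model: str = "TPM"
    # demography
    demog_n_sims: int = 4000
    demog_accept: float = 0.02
    demog_replicates: int = 2
    # inputs when not simulating
    genotypes_path: str = None
    sites_path: str = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        for key in ("genotypes_path", "sites_path"):
            value = getattr(cfg, key)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{key}: {value}")
        return cfg


def _place_sites(stack, n_sites, rng, margin=4):
    rows = rng.choice(np.arange(margin, stack.n_rows - margin),
                      size=n_sites, replace=False)
    cols = rng.choice(np.arange(margin, stack.n_cols - margin),
                      size=n_sites, replace=False)
    return resistance.FocalSites(
        [f"site{i + 1}" for i in range(n_sites)], rows, cols
    )


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in order; returns the artifact directory.

    Any stage failure aborts with the stage name and cause.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.info("config: %s", asdict(config))
    state = {}
    try:
        for stage in ALL_STAGES:
            if stage not in config.stages:
                continue
            seed = derive_seed(config.seed, stage)
            log.info("stage %s: seed %d", stage, seed)
            _STAGE_FNS[stage](config, state, seed, out)
    except Exception as err:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err
    finally:
        log.removeHandler(handler)
        handler.close()
    return out


def _provenance(config, stage, **extra):
    base = {"stage": stage, "seed": derive_seed(config.seed, stage),
            "global_seed": config.seed}
    if config.genotypes_path:
        base["genotypes"] = config.genotypes_path
    if config.sites_path:
        base["sites"] = config.sites_path
    base.update(extra)
    return base


def _stage_simulate(config, state, seed, out):
    rng = np.random.default_rng(seed)
    stack = synthetic.generate_landscape(
        config.n_rows, config.n_cols, config.cell_size, seed=seed
    )
    sites = _place_sites(stack, config.n_demes, rng)
    surfaces = resistance.candidate_surfaces(stack)
    matrices = resistance.resistance_matrices(surfaces, sites)
    truth = matrices[config.truth_variable]
    mig = synthetic.migration_from_resistance(truth, config.m0, config.alpha)
    # region labels split demes into contiguous blocks
    region_of = [f"region{1 + d * config.n_regions // config.n_demes}"
                 for d in range(config.n_demes)]
    params = synthetic.SimParams(
        n_demes=config.n_demes, deme_sizes=config.deme_size,
        migration=mig, mu=config.mu, n_loci=config.n_loci,
        burn_in=config.burn_in, sample_sizes=config.sample_size,
    )
    data = synthetic.simulate_metapopulation(
        params, seed=seed + 1, pop_labels=sites.ids,
        region_labels=region_of,
    )
    sio.write_genepop(data, out / "genotypes.gen")
    site_df = pd.DataFrame({
        "site": sites.ids,
        "x": (sites.cols + 0.5) * config.cell_size + 1e6,
        "y": (config.n_rows - 1 - sites.rows + 0.5) * config.cell_size + 1e6,
        "region": region_of,
    })
    sio.write_table(site_df, out / "sites.csv",
                    _provenance(config, "simulate",
                                truth_variable=config.truth_variable))
    for name in ("elevation", "slope", "canopy", "land_cover", "stream"):
        sio.write_ascii_grid(stack[name], out / f"{name}.asc",
                             cell_size=config.cell_size)
    state.update(stack=stack, sites=sites, surfaces=surfaces,
                 matrices=matrices, data=data, region_of=region_of)


def _require_data(config, state):
    if "data" not in state:
        if not config.genotypes_path:
            raise ValueError("no genotypes: run simulate or set "
                             "genotypes_path")
        region_map = None
        if config.sites_path:
            sites = sio.read_site_table(config.sites_path)
            state["site_table"] = sites
        state["data"] = sio.read_genepop(config.genotypes_path)
    return state["data"]


def _stage_stats(config, state, seed, out):
    data = _require_data(config, state)
    summaries = popgen.locus_summaries(data)
    sio.write_table(summaries, out / "locus_summaries.csv",
                    _provenance(config, "stats"))
    pops = data.populations
    hwe_rows = []
    for pop in pops:
        for locus in data.loci:
            g = data.genotypes(pop, locus)
            if len(g) >= 5 and len(np.unique(g.ravel())) >= 2:
                hwe_rows.append(
                    (pop, locus,
                     popgen.hwe_test(data, pop, locus, n_reps=400,
                                     seed=seed))
                )
    hwe = pd.DataFrame(hwe_rows, columns=["population", "locus", "p"])
    if len(hwe):
        hwe = pd.concat(
            [hwe,
             popgen.multiple_test_correction(
                 hwe["p"], "bonferroni", config.alpha_level
             )[["p_adjusted", "reject"]]],
            axis=1,
        )
    sio.write_table(hwe, out / "hwe.csv", _provenance(config, "stats"))
    for kind in ("FST", "GprimeST", "Dps"):
        m = popgen.pairwise_genetic_matrix(data, kind)
        sio.write_table(m.to_dataframe().reset_index(),
                        out / f"genetic_{kind.lower()}.csv",
                        _provenance(config, "stats", kind=kind))
        state[f"genetic_{kind}"] = m
    res = popgen.amova(data)
    amova_df = pd.DataFrame({
        "level": list(res.percentages),
        "variance": [res.components[k] for k in res.percentages],
        "percent": list(res.percentages.values()),
    })
    sio.write_table(amova_df, out / "amova.csv",
                    _provenance(config, "stats"))
    g = min(config.rarefaction_g,
            int(2 * summaries.loc[summaries.n > 0, "n"].min()))
    richness_table, richness_means = popgen.allelic_richness(data, g)
    sio.write_table(richness_table, out / "allelic_richness.csv",
                    _provenance(config, "stats", g=g))


def _stage_bottleneck(config, state, seed, out):
    data = _require_data(config, state)
    cfg = bn.BottleneckConfig(model=config.bottleneck_model,
                              n_equilibrium_reps=config.bottleneck_reps,
                              seed=seed)
    report = bn.bottleneck_report(data, cfg)
    sio.write_table(report, out / "bottleneck_summary.csv",
                    _provenance(config, "bottleneck",
                                model=config.bottleneck_model,
                                reps=config.bottleneck_reps))
    state["bottleneck"] = report


def _stage_resistance(config, state, seed, out):
    if "matrices" not in state:
        raise ValueError("resistance stage needs the simulate stage (or "
                         "precomputed matrices) in this run")
    for name, m in state["matrices"].items():
        sio.write_table(m.to_dataframe().reset_index(),
                        out / f"resistance_{name}.csv",
                        _provenance(config, "resistance", surface=name))


def _stage_regress(config, state, seed, out):
    data = _require_data(config, state)
    if "matrices" not in state:
        raise ValueError("regress stage needs resistance matrices")
    kind = config.distance_measure
    y_matrix = state.get(f"genetic_{kind}") or popgen.pairwise_genetic_matrix(
        data, kind
    )
    site_order = state["sites"].ids
    y = ms.unfold(y_matrix.reorder(site_order))
    candidates = {name: ms.unfold(m.reorder(site_order), name)
                  for name, m in state["matrices"].items()}
    corr = ms.predictor_correlation(candidates)
    sio.write_table(corr, out / "predictor_correlation.csv",
                    _provenance(config, "regress"))
    table = ms.all_subsets(y, candidates, max_size=3)
    ri = ms.relative_importance(table)
    ri_df = pd.DataFrame(
        sorted(ri.scores.items(), key=lambda kv: -kv[1]),
        columns=["variable", "RI"],
    )
    sio.write_table(ri_df, out / "ri_table.csv",
                    _provenance(config, "regress", measure=kind))
    combos = ms.select_for_multivariate(ri, config.ri_threshold)
    rows = []
    records = []
    for combo in combos:
        surf = resistance.standardize_and_sum(
            [state["surfaces"][v] for v in combo]
        )
        m = resistance.effective_resistance(surf, state["sites"])
        vec = ms.unfold(m.reorder(site_order), "+".join(combo))
        records.append(ms.fit_model(y, [vec]))
    table2 = ms._weight_and_sort(records)
    model_df = table2.to_dataframe()
    sio.write_table(model_df, out / "model_table.csv",
                    _provenance(config, "regress", measure=kind,
                                ri_threshold=config.ri_threshold))
    state["ri"] = ri
    state["model_table"] = table2


def _stage_demography(config, state, seed, out):
    data = _require_data(config, state)
    # pool each region into one sample; analyse the first region
    region = data.regions[0]
    pooled = data.subset(
        data.individuals["region"].to_numpy() == region
    ).merged_population(region)
    post = dem.infer_posterior(
        pooled, n_sims=config.demog_n_sims,
        accept_fraction=config.demog_accept,
        n_replicates=config.demog_replicates, seed=seed,
    )
    report = dem.report_table(post)
    report["classification"] = report.attrs["classification"]
    sio.write_table(report, out / "demography_report.csv",
                    _provenance(config, "demography",
                                region=region, n_sims=config.demog_n_sims))
    conv = dem.convergence_report(post)
    sio.write_table(conv, out / "demography_convergence.csv",
                    _provenance(config, "demography"))
    state["posterior"] = post


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "stats": _stage_stats,
    "bottleneck": _stage_bottleneck,
    "resistance": _stage_resistance,
    "regress": _stage_regress,
    "demography": _stage_demography,
}
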