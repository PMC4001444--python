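"""Scenario orchestration: initialization, neutral pre-evolution and six
selected generations of non-overlapping tree cohorts.

A scenario letter fixes the biology switches:

====  =============================================  ==========================
id    name                                           switches
====  =============================================  ==========================
A     neutral control                                h2 = 0
B     adaptive evolution                             h2 = 1
C     evolution without mortality                    mortality off
D     evolution without differential reproduction    equal fecundities
E     Type I mortality only                          end-of-year reserve check
F     Type II mortality only                         pre-budburst deficit check
G     reduced heritability                           h2 = 0.6
Ha    moderate frost effect on LAI                   frost_k = 0.1
Hb    strong frost effect on LAI                     frost_k = 0.2
====  =============================================  ==========================

Each generation lasts 70 years: a seedling stage (ages 0-39) that is not
simulated day by day — seeds jump from dormancy straight to age-40
recruits — and a 30-year adult stage driven by the 5-year climate sequence
repeated in six loops.  Adults grow for 20 years without reproducing, then
grow and reproduce over 10 years; at the end all survivors are removed and
the dormant seed pool is recruited to found the next generation.

One allelic-effects draw is shared by every repetition of a scenario; only
founder genotypes and positions change across repetitions.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import analysis, climate as climate_mod, demography as dem, genetics as gen, physiology as phys
from ._rng import stream

__all__ = [
    "SCENARIO_TABLE",
    "ScenarioConfig",
    "Population",
    "SimulationOutput",
    "initialize",
    "neutral_preevolution",
    "run_generation",
    "run_scenario",
]

SCENARIO_TABLE: dict[str, dict] = {
    "A": dict(h2=0.0, frost_k=0.0, mortality_mode=dem.MortalityMode.BOTH, differential_reproduction=True),
    "B": dict(h2=1.0, frost_k=0.0, mortality_mode=dem.MortalityMode.BOTH, differential_reproduction=True),
    "C": dict(h2=1.0, frost_k=0.0, mortality_mode=dem.MortalityMode.NONE, differential_reproduction=True),
    "D": dict(h2=1.0, frost_k=0.0, mortality_mode=dem.MortalityMode.BOTH, differential_reproduction=False),
    "E": dict(h2=1.0, frost_k=0.0, mortality_mode=dem.MortalityMode.TYPE_I_ONLY, differential_reproduction=True),
    "F": dict(h2=1.0, frost_k=0.0, mortality_mode=dem.MortalityMode.TYPE_II_ONLY, differential_reproduction=True),
    "G": dict(h2=0.6, frost_k=0.0, mortality_mode=dem.MortalityMode.BOTH, differential_reproduction=True),
    "Ha": dict(h2=1.0, frost_k=0.1, mortality_mode=dem.MortalityMode.BOTH, differential_reproduction=True),
    "Hb": dict(h2=1.0, frost_k=0.2, mortality_mode=dem.MortalityMode.BOTH, differential_reproduction=True),
}


@dataclass
class ScenarioConfig:
    """Full parameterisation of a scenario run (defaults follow the field
    parameter set of the simulated beech stand)."""

    scenario_id: str = "B"
    # genetics
    n_loci: int = 10
    mu_fcrit: float = 190.0     # degC, mean forcing requirement
    sigma2: float = 22.0        # (degC)^2, reference trait variance
    h2: float = 1.0
    # phenology / physiology
    t_base: float = 0.0
    rest_onset: int = 78
    t_min_effect: float = 0.0
    frost_k: float = 0.0
    sew: float = 60.0
    # mortality
    cum_cr_crit: float = 45.0
    bb_crit: float = 160.0
    mortality_mode: dem.MortalityMode = dem.MortalityMode.BOTH
    # reproduction
    s_b_res: float = 100.0
    r_sp: float = 0.05
    seed_cost: float = 0.45
    r_es: float = 0.33
    r_ss: float = 0.15
    r_sg: float = 0.485
    differential_reproduction: bool = True
    selfing_rate: float = 0.025
    gamma_m: float = 0.82
    # dispersal
    delta_p: float = 37.9
    b_p: float = 0.97
    delta_s: float = 18.13
    b_s: float = 0.31
    recruit_sd: float = 5.0     # m, Gaussian placement around an in-cell mother
    # recruit sizes
    mu_h: float = 9.0
    sd_h: float = 0.34
    mu_dbh: float = 13.8
    sd_dbh: float = 0.9
    # geometry / climate
    x_extent: float = 200.0
    y_extent: float = 1000.0
    cell_size: float = 20.0
    reference_elevation: float = 1200.0
    t_slope: float = -0.006
    tmin_slope: float = -0.006
    precip_slope: float = 0.0
    # schedule
    n_founders: int = 500
    n_generations: int = 6
    n_preevolution: int = 5
    n_repetitions: int = 21
    adult_years: int = 30
    repro_start_year: int = 21
    climate_block_years: int = 5
    # regulation (stand-density control; see docs/methods.md)
    max_population: int | None = 2000
    neutral_fecundity: float = 3.0
    record_annual: bool = False
    # test-harness hook: callable(pop, year) -> bool mask of trees to kill
    selection_hook: object | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.scenario_id not in SCENARIO_TABLE:
            raise ValueError(f"unknown scenario {self.scenario_id!r}")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        for name in ("r_es", "r_ss", "r_sg", "selfing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @classmethod
    def for_scenario(cls, scenario_id: str, **overrides) -> "ScenarioConfig":
        """Config with the scenario's switch table applied (overrides win)."""
        switches = dict(SCENARIO_TABLE[scenario_id])
        switches.update(overrides)
        return cls(scenario_id=scenario_id, **switches)

    # --- derived component parameter objects ---

    def domain(self) -> dem.Domain:
        return dem.Domain(self.x_extent, self.y_extent)

    def grid(self) -> dem.Grid:
        return dem.Grid(self.domain(), self.cell_size)

    def trait_model(self) -> gen.TraitModel:
        return gen.TraitModel(h2=self.h2, sigma2=self.sigma2, mu=self.mu_fcrit)

    def phenology(self) -> phys.PhenologyParams:
        return phys.PhenologyParams(
            t_base=self.t_base,
            rest_onset=self.rest_onset,
            frost_threshold=self.t_min_effect,
            frost_k=self.frost_k,
        )

    def carbon(self) -> phys.CarbonParams:
        return phys.CarbonParams(sew=self.sew)

    def lapse(self) -> climate_mod.LapseModel:
        return climate_mod.LapseModel(self.t_slope, self.tmin_slope, self.precip_slope)

    def pollen_kernel(self) -> dem.DispersalKernel:
        return dem.DispersalKernel(self.delta_p, self.b_p)

    def seed_kernel(self) -> dem.DispersalKernel:
        return dem.DispersalKernel(self.delta_s, self.b_s)

    def thresholds(self) -> dem.MortalityThresholds:
        return dem.MortalityThresholds(self.cum_cr_crit, self.bb_crit)

    def allometry(self) -> dem.AllometryParams:
        return dem.AllometryParams()


# elevational bands of the founder subpopulations (m)
FOUNDER_BANDS = ((790.0, 810.0), (990.0, 1010.0), (1190.0, 1210.0), (1390.0, 1410.0), (1590.0, 1610.0))


@dataclass
class Population:
    """A same-age cohort of trees as parallel arrays."""

    ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    dbh: np.ndarray
    height: np.ndarray
    genotypes: np.ndarray       # (n, n_loci) A1 counts
    genetic_value: np.ndarray   # degC
    f_crit: np.ndarray          # degC, lifetime phenotype
    mother: np.ndarray
    father: np.ndarray
    alive: np.ndarray
    cause: np.ndarray
    age: int = 40

    @property
    def n(self) -> int:
        return self.ids.size

    def elevation(self, domain: dem.Domain) -> np.ndarray:
        return np.asarray(domain.elevation(self.y), float)


def _draw_sizes(n: int, config: ScenarioConfig, rng: np.random.Generator):
    dbh = np.maximum(rng.normal(config.mu_dbh, config.sd_dbh, n), 0.5)
    height = np.maximum(rng.normal(config.mu_h, config.sd_h, n), 0.5)
    return dbh, height


def initialize(config: ScenarioConfig, effects: gen.AllelicEffects, rng: np.random.Generator) -> Population:
    """Found the population: equal subpopulations in five narrow elevational
    bands, Hardy-Weinberg genotypes at uniform allele frequencies, Gaussian
    recruit sizes, all trees 40 years old."""
    n = config.n_founders
    n_bands = len(FOUNDER_BANDS)
    per_band = n // n_bands
    counts = [per_band + (1 if i < n % n_bands else 0) for i in range(n_bands)]
    dom = config.domain()
    scale = dom.y_extent / (dom.elevation_top - dom.elevation_base)
    xs, ys = [], []
    for (lo, hi), cnt in zip(FOUNDER_BANDS, counts):
        xs.append(rng.uniform(0.0, dom.x_extent, cnt))
        ys.append(rng.uniform((lo - dom.elevation_base) * scale, (hi - dom.elevation_base) * scale, cnt))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    genotypes, _ = gen.init_founder_genotypes(n, config.n_loci, rng)
    gv = np.asarray(gen.genotypic_value(genotypes, effects), float)
    f_crit = np.asarray(gen.phenotype_fcrit(gv, config.trait_model(), rng), float)
    dbh, height = _draw_sizes(n, config, rng)
    return Population(
        ids=np.arange(n),
        x=x,
        y=y,
        dbh=dbh,
        height=height,
        genotypes=genotypes,
        genetic_value=gv,
        f_crit=f_crit,
        mother=np.full(n, -1),
        father=np.full(n, -1),
        alive=np.ones(n, bool),
        cause=np.zeros(n, np.int8),
        age=40,
    )


def _mate_and_disperse(
    pop: Population,
    fecundity: np.ndarray,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One round of seed rain and mating for living adults.

    Returns ``(mothers, fathers, cells)`` index arrays, one entry per seed;
    fathers are drawn from that round's pollen pool (selfing gate first).
    """
    grid = config.grid()
    pk = config.pollen_kernel()
    sk = config.seed_kernel()
    alive_idx = np.flatnonzero(pop.alive)
    mothers_out, fathers_out, cells_out = [], [], []
    for j in alive_idx:
        fj = fecundity[j]
        if fj <= 0.0:
            continue
        tau = dem.seed_rain(pop.x[j], pop.y[j], fj, grid, sk)
        counts = dem.recruit_counts(tau, grid.cell_area, rng)
        total = int(counts.sum())
        if total == 0:
            continue
        if alive_idx.size > 1:
            w = dem.density_with_images(pk, pop.x[alive_idx], pop.y[alive_idx], pop.x[j], pop.y[j], grid.domain)
            w = w * pop.dbh[alive_idx] ** config.gamma_m
            w[alive_idx == j] = 0.0
            w_sum = w.sum()
            if w_sum <= 0:
                continue
            fathers_local = rng.choice(alive_idx, size=total, p=w / w_sum)
        elif config.selfing_rate > 0.0:
            fathers_local = np.full(total, j)
        else:
            warnings.warn("no candidate fathers and selfing disabled; seeds skipped")
            continue
        if config.selfing_rate > 0.0:
            fathers_local[rng.random(total) < config.selfing_rate] = j
        cells = np.repeat(np.arange(grid.n_cells), counts)
        mothers_out.append(np.full(total, j))
        fathers_out.append(fathers_local)
        cells_out.append(cells)
    if not mothers_out:
        empty = np.empty(0, int)
        return empty, empty.copy(), empty.copy()
    return (
        np.concatenate(mothers_out),
        np.concatenate(fathers_out),
        np.concatenate(cells_out),
    )


def _make_recruits(
    pop: Population,
    mothers: np.ndarray,
    fathers: np.ndarray,
    cells: np.ndarray,
    config: ScenarioConfig,
    effects: gen.AllelicEffects,
    rng: np.random.Generator,
    id_start: int,
    thin: bool = True,
) -> Population:
    """Instantiate age-40 recruits from seed records, then apply crown thinning
    and the population cap."""
    n = mothers.size
    grid = config.grid()
    genotypes = gen.cross(pop.genotypes[mothers], pop.genotypes[fathers], rng)
    gv = np.asarray(gen.genotypic_value(genotypes, effects), float)
    f_crit = np.asarray(gen.phenotype_fcrit(gv, config.trait_model(), rng), float)
    dbh, height = _draw_sizes(n, config, rng)
    x = np.empty(n)
    y = np.empty(n)
    for i in range(n):
        x[i], y[i] = dem.place_recruit(
            int(cells[i]),
            grid,
            rng,
            mother_xy=(pop.x[mothers[i]], pop.y[mothers[i]]),
            mother_sd=config.recruit_sd,
        )
    keep = np.ones(n, bool)
    if thin:
        crown = np.asarray(dem.crown_area_from_dbh(dbh, config.allometry()), float)
        keep = dem.crown_overlap_thinning(x, y, crown, rng)
    if config.max_population is not None and keep.sum() > config.max_population:
        kept_idx = np.flatnonzero(keep)
        drop = rng.choice(kept_idx, size=int(keep.sum()) - config.max_population, replace=False)
        keep[drop] = False
    idx = np.flatnonzero(keep)
    m = idx.size
    return Population(
        ids=id_start + np.arange(m),
        x=x[idx],
        y=y[idx],
        dbh=dbh[idx],
        height=height[idx],
        genotypes=genotypes[idx],
        genetic_value=gv[idx],
        f_crit=f_crit[idx],
        mother=pop.ids[mothers[idx]],
        father=pop.ids[fathers[idx]],
        alive=np.ones(m, bool),
        cause=np.zeros(m, np.int8),
        age=40,
    )


def neutral_preevolution(
    pop: Population,
    config: ScenarioConfig,
    effects: gen.AllelicEffects,
    rng: np.random.Generator,
    n_gen: int | None = None,
    id_start: int = 0,
) -> tuple[Population, int]:
    """Generations of drift and gene flow without selection.

    All adults survive and reproduce with equal fecundity; mating and seed
    dispersal operate normally, building spatial genetic structure and
    among-band differentiation; recruits are uniformly subsampled back to
    the founder population size (physiology is bypassed entirely)."""
    n_gen = config.n_preevolution if n_gen is None else n_gen
    next_id = id_start if id_start > pop.ids.max(initial=-1) else int(pop.ids.max()) + 1
    for _ in range(n_gen):
        fec = np.full(pop.n, config.neutral_fecundity)
        mothers, fathers, cells = _mate_and_disperse(pop, fec, config, rng)
        if mothers.size == 0:
            raise RuntimeError("neutral pre-evolution produced no seeds")
        if mothers.size > config.n_founders:
            sel = rng.choice(mothers.size, config.n_founders, replace=False)
            mothers, fathers, cells = mothers[sel], fathers[sel], cells[sel]
        pop = _make_recruits(
            pop, mothers, fathers, cells, config, effects, rng, next_id, thin=False
        )
        next_id = int(pop.ids.max()) + 1
    return pop, next_id


def _adult_climate(config: ScenarioConfig, base: climate_mod.ClimateSeries) -> climate_mod.ClimateSeries:
    n_loops = int(np.ceil(config.adult_years / base.n_years))
    return climate_mod.loop_sequence(base, n_loops)


def run_generation(
    pop: Population,
    config: ScenarioConfig,
    effects: gen.AllelicEffects,
    base_climate: climate_mod.ClimateSeries,
    rng: np.random.Generator,
    generation: int = 0,
    rep: int = 0,
    next_id: int | None = None,
    collector: "Records | None" = None,
) -> tuple[Population | None, int]:
    """One 70-year generation: 30 adult years of daily physiology, growth,
    carbon-starvation mortality, reproduction in the last 10 adult years,
    then recruitment of the dormant seed pool.  Returns ``(next cohort or
    None on collapse, next id)``."""
    if next_id is None:
        next_id = int(pop.ids.max()) + 1
    looped = _adult_climate(config, base_climate)
    lapse = config.lapse()
    dom = config.domain()
    allom = config.allometry()
    phen = config.phenology()
    carbon = config.carbon()
    thresholds = config.thresholds()
    elev = pop.elevation(dom)
    dt = lapse.t_slope * (elev - base_climate.reference_elevation)
    dtmin = lapse.tmin_slope * (elev - base_climate.reference_elevation)

    crown = np.asarray(dem.crown_area_from_dbh(pop.dbh, allom), float)
    state = phys.init_state(
        pop.n, carbon, b_tree=np.asarray(dem.stem_carbon(pop.dbh, pop.height, allom), float) / np.maximum(crown, 1e-9)
    )

    if collector is not None:
        collector.start_of_generation(rep, generation, pop, dom)

    seed_records: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    tbb_first_block: list[np.ndarray] = []

    for year in range(1, config.adult_years + 1):
        alive_idx = np.flatnonzero(pop.alive)
        if alive_idx.size == 0:
            break
        wx = looped.year(year - 1)
        sub = state.subset(alive_idx)
        summary, _ = phys.run_year(
            sub,
            wx["t_mean"][None, :] + dt[alive_idx, None],
            wx["t_min"][None, :] + dtmin[alive_idx, None],
            np.maximum(wx["precip"] + lapse.precip_slope * (elev[alive_idx, None] - base_climate.reference_elevation), 0.0),
            pop.f_crit[alive_idx],
            phen,
            carbon,
        )
        state.write_back(alive_idx, sub)

        if year <= base_climate.n_years:
            tbb_full = np.full(pop.n, np.nan)
            tbb_full[alive_idx] = summary.tbb
            tbb_first_block.append(tbb_full)

        # growth before the survival verdict: the year's wood is laid down
        crown_alive = np.asarray(dem.crown_area_from_dbh(pop.dbh[alive_idx], allom), float)
        wood_g = summary.wood * crown_alive
        new_dbh = np.asarray(dem.dbh_growth(pop.dbh[alive_idx], pop.height[alive_idx], wood_g, allom), float)
        pop.dbh[alive_idx] = new_dbh
        pop.height[alive_idx] = np.asarray(dem.height_from_dbh(new_dbh, allom), float)

        ok, cause = dem.mortality_check(summary.cum_cr, summary.bb_deficit, thresholds, config.mortality_mode)
        died = alive_idx[~ok]
        pop.alive[died] = False
        pop.cause[died] = cause[~ok]

        if config.selection_hook is not None:
            kill = np.asarray(config.selection_hook(pop, year), bool)
            pop.alive[kill] = False

        fec_row = None
        if year >= config.repro_start_year:
            survivors = np.flatnonzero(pop.alive)
            n_seeds = np.zeros(pop.n, dtype=np.int64)
            if survivors.size:
                crown_surv = np.asarray(dem.crown_area_from_dbh(pop.dbh[survivors], allom), float)
                ns, debit = dem.primary_seed_production(
                    state.b_res[survivors], crown_surv, config.s_b_res, config.r_sp, config.seed_cost
                )
                state.b_res[survivors] -= debit
                n_seeds[survivors] = ns
            fec = np.zeros(pop.n)
            fec[survivors] = np.asarray(
                dem.effective_fecundity(n_seeds[survivors], config.r_es, config.r_ss, config.r_sg), float
            )
            if not config.differential_reproduction and survivors.size:
                fec[survivors] = fec[survivors].mean()
            fec_row = fec
            mothers, fathers, cells = _mate_and_disperse(pop, fec, config, rng)
            if mothers.size:
                seed_records.append((mothers, fathers, cells))

        if collector is not None:
            collector.annual(rep, generation, year, pop, summary, alive_idx, fec_row)

    if collector is not None:
        collector.end_of_generation(rep, generation, pop, dom, tbb_first_block, base_climate.n_years)

    if not seed_records:
        return None, next_id
    mothers = np.concatenate([s[0] for s in seed_records])
    fathers = np.concatenate([s[1] for s in seed_records])
    cells = np.concatenate([s[2] for s in seed_records])
    pool_cap = None if config.max_population is None else 3 * config.max_population
    if pool_cap is not None and mothers.size > pool_cap:
        sel = rng.choice(mothers.size, pool_cap, replace=False)
        mothers, fathers, cells = mothers[sel], fathers[sel], cells[sel]
    new_pop = _make_recruits(pop, mothers, fathers, cells, config, effects, rng, next_id)
    if new_pop.n == 0:
        return None, next_id
    return new_pop, int(new_pop.ids.max()) + 1


class Records:
    """Collects tidy per-generation records during a scenario run."""

    def __init__(self, record_annual: bool = False):
        self.band_rows: list[dict] = []
        self.pop_rows: list[dict] = []
        self.tbb_rows: list[dict] = []
        self.tree_rows: list[dict] = []
        self.annual_rows: list[dict] = []
        self.fecundity_rows: list[dict] = []
        self.record_annual = record_annual
        self._start: dict[tuple[int, int], dict] = {}

    def start_of_generation(self, rep, generation, pop: Population, dom: dem.Domain):
        elev = pop.elevation(dom)
        bands = analysis.assign_bands(elev)
        self._start[(rep, generation)] = {
            "bands": bands,
            "f_crit": pop.f_crit.copy(),
            "genetic": pop.genetic_value.copy(),
            "elev": elev,
            "ids": pop.ids.copy(),
        }

    def annual(self, rep, generation, year, pop, summary, alive_idx, fec):
        if fec is not None:
            live = np.flatnonzero(pop.alive)
            if live.size:
                self.fecundity_rows.append(
                    {"rep": rep, "generation": generation, "year": year,
                     "n": int(live.size),
                     "f_min": float(fec[live].min()), "f_max": float(fec[live].max()),
                     "f_mean": float(fec[live].mean())}
                )
        if self.record_annual:
            for k, i in enumerate(alive_idx):
                self.annual_rows.append(
                    {"rep": rep, "generation": generation, "year": year,
                     "tree_id": int(pop.ids[i]), "tbb": float(summary.tbb[k]),
                     "lgs": float(summary.lgs[k]), "wsi": float(summary.wsi[k]),
                     "gpp": float(summary.gpp[k]), "respiration": float(summary.respiration[k]),
                     "cum_cr": float(summary.cum_cr[k]), "bb_deficit": float(summary.bb_deficit[k])}
                )

    def end_of_generation(self, rep, generation, pop: Population, dom, tbb_block, n_clim_years):
        start = self._start[(rep, generation)]
        bands = start["bands"]
        surv = pop.alive
        elev = start["elev"]
        self.pop_rows.append(
            {"rep": rep, "generation": generation, "n_start": int(pop.n),
             "n_end": int(surv.sum()), "mean_elev_start": float(elev.mean())}
        )
        for b in range(1, analysis.N_BANDS + 1):
            in_band = bands == b
            nb = int(in_band.sum())
            row = {"rep": rep, "generation": generation, "band": b, "n_start": nb}
            if nb:
                row["mean_fcrit_start"] = float(start["f_crit"][in_band].mean())
                row["mean_genetic_start"] = float(start["genetic"][in_band].mean())
                row["mean_elev_start"] = float(elev[in_band].mean())
            sb = in_band & surv
            row["n_end"] = int(sb.sum())
            if sb.sum():
                row["mean_fcrit_end"] = float(pop.f_crit[sb].mean())
                row["vp_end"] = float(np.var(pop.f_crit[sb], ddof=1)) if sb.sum() > 1 else np.nan
            self.band_rows.append(row)
            for yy in range(min(len(tbb_block), n_clim_years)):
                vals = tbb_block[yy][in_band]
                vals = vals[~np.isnan(vals)]
                if vals.size:
                    self.tbb_rows.append(
                        {"rep": rep, "generation": generation, "band": b,
                         "clim_year": yy, "mean_tbb": float(vals.mean()), "n": int(vals.size)}
                    )
        for i in range(pop.n):
            self.tree_rows.append(
                {"rep": rep, "generation": generation, "id": int(pop.ids[i]),
                 "x": float(pop.x[i]), "y": float(pop.y[i]),
                 "elevation": float(elev[i]), "band": int(bands[i]),
                 "f_crit": float(pop.f_crit[i]), "genetic_value": float(pop.genetic_value[i]),
                 "dbh": float(pop.dbh[i]),
                 "mother": int(pop.mother[i]), "father": int(pop.father[i]),
                 "alive_end": bool(pop.alive[i]), "cause": int(pop.cause[i])}
            )


@dataclass
class SimulationOutput:
    """Tidy result tables of a multi-repetition scenario run."""

    config: ScenarioConfig
    master_seed: int
    band_stats: pd.DataFrame
    pop_stats: pd.DataFrame
    tbb_stats: pd.DataFrame
    trees: pd.DataFrame
    fecundity: pd.DataFrame
    annual: pd.DataFrame
    collapsed_reps: list[int]


def run_scenario(config: ScenarioConfig, master_seed: int) -> SimulationOutput:
    """Run ``n_repetitions`` seeded repetitions of a scenario.

    Allelic effects are drawn once and shared; each repetition redraws the
    founder genotypes and positions.  The synthetic base climate is likewise
    drawn once (the same weather drives every repetition)."""
    effects = gen.draw_allelic_effects(config.n_loci, config.mu_fcrit, stream(master_seed, "effects"))
    base_climate = climate_mod.generate_base_series(
        config.climate_block_years,
        stream(master_seed, "climate"),
        reference_elevation=config.reference_elevation,
    )
    records = Records(record_annual=config.record_annual)
    collapsed: list[int] = []
    for rep in range(config.n_repetitions):
        pop = initialize(config, effects, stream(master_seed, "rep", rep, "founders"))
        pop, next_id = neutral_preevolution(
            pop, config, effects, stream(master_seed, "rep", rep, "preevolution")
        )
        sim_rng = stream(master_seed, "rep", rep, "simulation")
        for g in range(config.n_generations):
            pop, next_id = run_generation(
                pop, config, effects, base_climate, sim_rng,
                generation=g, rep=rep, next_id=next_id, collector=records,
            )
            if pop is None:
                collapsed.append(rep)
                break
    return SimulationOutput(
        config=config,
        master_seed=master_seed,
        band_stats=pd.DataFrame(records.band_rows),
        pop_stats=pd.DataFrame(records.pop_rows),
        tbb_stats=pd.DataFrame(records.tbb_rows),
        trees=pd.DataFrame(records.tree_rows),
        fecundity=pd.DataFrame(records.fecundity_rows),
        annual=pd.DataFrame(records.annual_rows),
        collapsed_reps=collapsed,
    )
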