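"""Simulation scheduler and experiment drivers.

``run_simulation`` advances a closed island population from 15 September of
year 0 (the start of the first managed oestrous period) for a 3-year
horizon, or until extinction.  Each simulated day applies, in order:
date-triggered events (oestrous window transitions, decoy deployment,
births on 30 October, dam oestrus onset 10 days later, kit dispersal on
16 January), the 16-step nocturnal movement/encounter/trapping loop, and
end-of-day natural mortality.

``run_scenarios`` estimates eradication probabilities for the four
management scenarios (nothing, traps only, decoys only, traps + decoys)
from independent realisations and applies the Allee-inference logic: a
component (mate-finding) Allee effect is indicated when traps + decoys
out-eradicates traps alone, a demographic Allee effect when decoys alone
out-eradicate doing nothing.  Scenarios share per-replicate seeds (common
random numbers), which sharpens the paired comparisons without biasing the
marginal probabilities.

``run_sensitivity`` performs the global sweep: each iteration draws the
eight swept parameters uniformly from their ranges, runs one realisation
with both traps and decoys active, and records the binary eradication
outcome for downstream logistic regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calendar as cal
from . import life_history as lh
from ._kernel import GridIndex, _EMPTY_GRID, run_night as _run_night_kernel
from .config import SWEEP_RANGES, SimConfig
from .geometry import (IslandGeometry, make_point_grid, make_synthetic_island,
                       make_trap_network)
from .management import DecoyDeployment


@dataclass
class Landscape:
    """Static geometry shared across realisations: island, traps, decoys."""

    island: IslandGeometry
    traps_xy: np.ndarray
    decoys_xy: np.ndarray
    poly_x: np.ndarray = field(init=False)
    poly_y: np.ndarray = field(init=False)
    trap_grid: GridIndex = field(init=False)
    decoy_grid: GridIndex = field(init=False)

    def __post_init__(self):
        self.poly_x, self.poly_y = self.island.boundary_arrays()
        self.traps_xy = np.asarray(self.traps_xy, dtype=np.float64).reshape(-1, 2)
        self.decoys_xy = np.asarray(self.decoys_xy, dtype=np.float64).reshape(-1, 2)
        self.trap_grid = GridIndex(self.traps_xy, 250.0) \
            if len(self.traps_xy) else _EMPTY_GRID
        # decoy cells must span the detection radius so a 3x3 scan suffices
        self.decoy_grid = GridIndex(self.decoys_xy, 2500.0) \
            if len(self.decoys_xy) else _EMPTY_GRID


def build_landscape(config: SimConfig,
                    island: IslandGeometry | None = None) -> Landscape:
    """Assemble the island, trap network and decoy grid for a config."""
    if island is None:
        island = make_synthetic_island(config.island_area_km2,
                                       config.island_elongation,
                                       config.island_seed)
    traps = make_trap_network(island, config.trap_target_count).xy \
        if config.traps_on else np.empty((0, 2))
    decoys = make_point_grid(island, config.decoy_spacing) \
        if config.decoys_on else np.empty((0, 2))
    return Landscape(island, traps, decoys)


@dataclass
class World:
    """Mutable simulation state for one realisation."""

    config: SimConfig
    landscape: Landscape
    pop: lh.Population
    nests: lh.NestLedger
    decoy_state: DecoyDeployment
    rng: np.random.Generator
    day_index: int = 0
    births_total: int = 0
    trap_deaths: int = 0
    natural_deaths: int = 0
    conceptions: int = 0

    @property
    def year(self) -> int:
        return cal.to_date(self.day_index)[0]

    @property
    def doy(self) -> int:
        return cal.to_date(self.day_index)[1]

    @property
    def island(self) -> IslandGeometry:
        return self.landscape.island

    @property
    def traps_xy(self) -> np.ndarray:
        return self.landscape.traps_xy

    @property
    def decoys_xy(self) -> np.ndarray:
        return self.landscape.decoys_xy


@dataclass(frozen=True)
class SimResult:
    """Outcome of one realisation."""

    eradicated: bool
    extinction_day: int | None
    final_count: int
    initial_n: int
    births_total: int
    trap_deaths: int
    natural_deaths: int
    conceptions: int
    population_series: np.ndarray | None = None


class ScenarioResult(dict):
    """Eradication probabilities per scenario with binomial standard errors
    and the Allee-effect verdicts."""

    SCENARIOS = ("none", "trap_only", "decoy_only", "trap_decoy")

    @property
    def component_allee(self) -> bool:
        return self["trap_decoy"]["p"] > self["trap_only"]["p"]

    @property
    def demographic_allee(self) -> bool:
        return self["decoy_only"]["p"] > self["none"]["p"]


def make_world(config: SimConfig, rng: np.random.Generator,
               landscape: Landscape | None = None) -> World:
    if landscape is None:
        landscape = build_landscape(config)
    pop = lh.init_population(rng, config, landscape.island)
    return World(config=config, landscape=landscape, pop=pop,
                 nests=lh.NestLedger(),
                 decoy_state=DecoyDeployment(config.n_deployments), rng=rng)


def run_night(world: World) -> tuple[int, int]:
    """One night of the compiled 16-step loop; returns (trap deaths,
    conceptions)."""
    cfg = world.config
    ls = world.landscape
    pop = world.pop
    n = pop.n
    doy = world.doy
    oestrus = cal.in_oestrous_window(doy)
    traps_live = cfg.traps_on and cal.traps_active(doy) and len(ls.traps_xy) > 0
    dep = world.decoy_state
    dec_on = cfg.decoys_on and dep.active and len(ls.decoys_xy) > 0
    dec_w = dep.weight(world.day_index, cfg.gamma) if dec_on else 0.0
    dg = ls.decoy_grid
    tg = ls.trap_grid
    trap_deaths, conceptions = _run_night_kernel(
        world.rng, n, pop.male[:n], pop.x[:n], pop.y[:n], pop.hx[:n],
        pop.hy[:n], pop.alive[:n], pop.ms[:n], pop.attractive[:n],
        pop.pregnant[:n], pop.nursing[:n], pop.hab_code[:n], pop.hab_exp[:n],
        pop.death_cause[:n],
        world.nests.x, world.nests.y, world.nests.fem, world.nests.mated,
        world.nests.fem_pregnant, world.nests.alive,
        dec_on, dg.x, dg.y, dec_w,
        dg.start, dg.items, dg.x0, dg.y0, dg.cell, dg.nx, dg.ny,
        traps_live, tg.x, tg.y,
        tg.start, tg.items, tg.x0, tg.y0, tg.cell, tg.nx, tg.ny,
        ls.poly_x, ls.poly_y,
        cfg.alpha, cfg.delta, cfg.min_k, cfg.base_scale,
        cfg.detection_radius, cfg.encounter_radius_mate,
        cfg.encounter_radius_trap, cfg.capture_prob, cfg.p_pregnancy,
        cfg.habituation_days, world.day_index, cfg.steps_per_night,
        oestrus, cfg.boundary_max_tries, cfg.encounter_selected_only)
    return trap_deaths, conceptions


def run_day(world: World) -> None:
    """Advance one full day: dated events, the night loop, then mortality."""
    cfg = world.config
    pop = world.pop
    year, doy = cal.to_date(world.day_index)

    # --- date-triggered events, before any movement ---
    if doy == cal.DISPERSAL_DAY:
        world.births_total += lh.disperse_nests(
            pop, world.nests, world.island, world.rng, year)
    lh.update_states(pop, doy)
    world.decoy_state.update(world.day_index, doy, cfg.decoys_on)
    if doy == cal.BIRTH_DAY:
        due = np.flatnonzero(pop.alive[:pop.n] & pop.pregnant[:pop.n]
                             & (pop.due_year[:pop.n] == year))
        for dam in due:
            lh.give_birth(pop, world.nests, int(dam), world.rng, cfg)

    # --- nocturnal movement, encounters, trapping ---
    active = cal.in_oestrous_window(doy) \
        or (cfg.traps_on and cal.traps_active(doy)) \
        or cfg.simulate_idle_nights
    if active and pop.alive_count() > 0:
        prev_pregnant = pop.pregnant[:pop.n].copy()
        trap_deaths, conceptions = run_night(world)
        world.trap_deaths += trap_deaths
        world.conceptions += conceptions
        # kernel deaths: a trapped nursing dam loses her litter
        if trap_deaths:
            dead_dams = np.flatnonzero(~pop.alive[:pop.n] & pop.nursing[:pop.n])
            for dam in dead_dams:
                lh.kill(pop, int(dam), lh.TRAP_DEATH, world.nests)
                pop.alive[dam] = False
        # stamp due dates on females fertilised tonight
        newly = np.flatnonzero(pop.pregnant[:pop.n] & ~prev_pregnant)
        if len(newly):
            due_year, _ = lh.implantation_due_date(year, doy)
            pop.due_year[newly] = due_year

    # --- end-of-day natural mortality ---
    deaths, _kit_losses = lh.apply_natural_mortality(
        pop, world.nests, cfg.p_daily_survival, world.rng)
    world.natural_deaths += deaths
    world.day_index += 1


def run_simulation(config: SimConfig, seed,
                   landscape: Landscape | None = None,
                   track_population: bool = False) -> SimResult:
    """Run one realisation to the horizon or extinction (deterministic
    given the seed)."""
    rng = np.random.default_rng(seed)
    world = make_world(config, rng, landscape)
    initial_n = world.pop.n
    horizon = config.horizon_days
    series = np.zeros(horizon + 1, dtype=np.int64) if track_population else None
    if track_population:
        series[0] = world.pop.alive_count()
    extinction_day = None
    for day in range(horizon):
        run_day(world)
        count = world.pop.alive_count()
        if track_population:
            series[day + 1] = count
        if count == 0:
            extinction_day = world.day_index
            break
        if config.max_population is not None and count > config.max_population:
            break  # eradication is out of reach; outcome already decided
    final = world.pop.alive_count()
    return SimResult(
        eradicated=final == 0,
        extinction_day=extinction_day,
        final_count=final,
        initial_n=initial_n,
        births_total=world.births_total,
        trap_deaths=world.trap_deaths,
        natural_deaths=world.natural_deaths,
        conceptions=world.conceptions,
        population_series=None if series is None else series[: (extinction_day
                                                                or horizon) + 1],
    )


def _child_seed(seed: int, rep: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed), int(rep)])


SCENARIO_FLAGS = {
    "none": dict(traps_on=False, decoys_on=False),
    "trap_only": dict(traps_on=True, decoys_on=False),
    "decoy_only": dict(traps_on=False, decoys_on=True),
    "trap_decoy": dict(traps_on=True, decoys_on=True),
}


def run_scenarios(config: SimConfig, n_reps: int = 400, seed: int = 0,
                  scenarios=None, island: IslandGeometry | None = None,
                  progress: bool = False) -> ScenarioResult:
    """Estimate eradication probability per management scenario.

    Replicate ``r`` of every scenario uses the same child seed, so the four
    estimates are positively correlated (paired comparisons between
    scenarios are sharper than the marginal binomial errors suggest).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    if island is None:
        island = make_synthetic_island(config.island_area_km2,
                                       config.island_elongation,
                                       config.island_seed)
    result = ScenarioResult()
    for name in scenarios or ScenarioResult.SCENARIOS:
        scen_cfg = config.replace(**SCENARIO_FLAGS[name])
        landscape = build_landscape(scen_cfg, island)
        outcomes = np.zeros(n_reps, dtype=bool)
        for r in range(n_reps):
            res = run_simulation(scen_cfg, _child_seed(seed, r), landscape)
            outcomes[r] = res.eradicated
            if progress and (r + 1) % 50 == 0:
                print(f"  {name}: {r + 1}/{n_reps}", flush=True)
        p = outcomes.mean()
        result[name] = {
            "p": float(p),
            "se": float(math.sqrt(p * (1 - p) / n_reps)),
            "eradications": int(outcomes.sum()),
            "n_reps": n_reps,
        }
    return result


def sample_sweep_parameters(rng: np.random.Generator) -> dict:
    """One uniform draw of the eight swept parameters."""
    lo_n, hi_n = SWEEP_RANGES["initial_n"]
    lo_h, hi_h = SWEEP_RANGES["habituation_days"]
    return {
        "initial_n": int(rng.integers(lo_n, hi_n + 1)),
        "decoy_spacing": float(rng.uniform(*SWEEP_RANGES["decoy_spacing"])),
        "n_deployments": int(rng.integers(1, 3)),
        "alpha": float(rng.uniform(*SWEEP_RANGES["alpha"])),
        "delta": float(rng.uniform(*SWEEP_RANGES["delta"])),
        "gamma": float(rng.uniform(*SWEEP_RANGES["gamma"])),
        "habituation_days": int(rng.integers(lo_h, hi_h + 1)),
        "p_daily_survival": float(rng.uniform(*SWEEP_RANGES["p_daily_survival"])),
    }


SWEEP_COLUMNS = ("initial_n", "decoy_spacing", "n_deployments", "alpha",
                 "delta", "gamma", "habituation_days", "p_daily_survival")


def run_sensitivity(n_iter: int = 5000, seed: int = 0,
                    config_template: SimConfig | None = None,
                    island: IslandGeometry | None = None,
                    progress: bool = False) -> pd.DataFrame:
    """Global sensitivity sweep with traps and decoys active.

    Each row holds the eight sampled parameter values, the child seed, and
    the binary eradication outcome of one independent realisation.  Trap
    and island geometry are fixed across iterations; the decoy grid is
    rebuilt per iteration to match the sampled spacing.  Runs that exceed
    500 animals are recorded as failures without simulating further (from
    there eradication within the horizon is unreachable).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    template = config_template or SimConfig()
    template = template.replace(traps_on=True, decoys_on=True,
                                max_population=500)
    if island is None:
        island = make_synthetic_island(template.island_area_km2,
                                       template.island_elongation,
                                       template.island_seed)
    traps = make_trap_network(island, template.trap_target_count).xy
    master = np.random.default_rng(seed)
    rows = []
    for it in range(n_iter):
        params = sample_sweep_parameters(master)
        child = int(master.integers(0, 2**31 - 1))
        cfg = template.replace(**params)
        landscape = Landscape(island, traps,
                              make_point_grid(island, cfg.decoy_spacing))
        res = run_simulation(cfg, child, landscape)
        rows.append({**params, "seed": child,
                     "eradicated": int(res.eradicated)})
        if progress and (it + 1) % 100 == 0:
            print(f"  sweep: {it + 1}/{n_iter}", flush=True)
    return pd.DataFrame(rows)
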