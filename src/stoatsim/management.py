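"""Trapping sessions, pheromone-decoy deployment and interaction rules.

Traps run in three 14-day baited sessions per year (from 20 January,
20 July and 20 November); an active trap within 15 m of a stoat at the end
of a movement step captures it with probability 0.2.  Pheromone decoys are
deployed on every grid point on 15 September (and refreshed on 15 November
under a two-deployment regime); their attractiveness decays exponentially
at rate γ per day since deployment, and they are inert outside the
oestrous window.

The Python-level operations here mirror the engine kernel's compiled
per-step logic on a :class:`~stoatsim.engine.World`; they are the readable
reference used in tests and small interactive work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import calendar as cal
from . import life_history as lh
from .movement import mate_search_kappa

# re-export the schedule predicate at its natural home
traps_active = cal.traps_active


@dataclass
class DecoyDeployment:
    """State of the decoy network through one simulation."""

    n_deployments: int = 2
    active: bool = False
    deploy_day: int = -1  # absolute day index of the latest deployment

    def __post_init__(self):
        if self.n_deployments not in (1, 2):
            raise ValueError("n_deployments must be 1 or 2")

    def update(self, day_index: int, doy: int, decoys_on: bool) -> None:
        if not decoys_on:
            return
        if doy == cal.OESTRUS_START:
            self.active = True
            self.deploy_day = day_index
        elif doy == cal.REDEPLOY_DAY and self.active and self.n_deployments == 2:
            self.deploy_day = day_index  # refresh: age resets to zero
        elif not cal.in_oestrous_window(doy):
            self.active = False

    def age_days(self, day_index: int) -> int:
        if not self.active:
            raise ValueError("no active deployment")
        return day_index - self.deploy_day

    def weight(self, day_index: int, gamma: float) -> float:
        """Shared temporal attractiveness factor exp(-gamma * age)."""
        return math.exp(-gamma * self.age_days(day_index)) if self.active else 0.0


@dataclass(frozen=True)
class CoaCandidate:
    """One potential centre of attraction visible to a mate-searching stoat."""

    target_id: int
    kind: str            # "mate" | "nest" | "decoy"
    distance: float      # m
    age_days: int        # days since deployment; 0 for live animals
    kappa: float


def visible_coas(world, i: int) -> list[CoaCandidate]:
    """All COA candidates for mate-searching stoat ``i``: opposite-sex
    receptive stoats, nests with unmated female kits (males only) and
    active decoys, within the detection radius and not under habituation.
    """
    pop = world.pop
    cfg = world.config
    if not pop.ms[i]:
        raise ValueError("visible_coas is defined for mate-searching stoats")
    day = world.day_index
    out: list[CoaCandidate] = []
    xi, yi = pop.x[i], pop.y[i]

    def dist(px, py):
        return math.hypot(px - xi, py - yi)

    for j in range(pop.n):
        if j == i or not pop.alive[j] or pop.male[j] == pop.male[i] \
                or not pop.attractive[j]:
            continue
        d = dist(pop.x[j], pop.y[j])
        if d <= cfg.detection_radius and not lh.is_habituated(
                pop, i, lh.STOAT_CODE_BASE + j, day):
            out.append(CoaCandidate(
                j, "mate", d, 0,
                mate_search_kappa(d, 0, cfg.delta, cfg.gamma, cfg.min_k)))
    if pop.male[i]:
        nests = world.nests
        for j in range(len(nests)):
            if not nests.alive[j] or nests.mated[j] or nests.fem[j] == 0:
                continue
            d = dist(nests.x[j], nests.y[j])
            if d <= cfg.detection_radius and not lh.is_habituated(
                    pop, i, lh.NEST_CODE_BASE + j, day):
                out.append(CoaCandidate(
                    j, "nest", d, 0,
                    mate_search_kappa(d, 0, cfg.delta, cfg.gamma, cfg.min_k)))
    dep = world.decoy_state
    if world.config.decoys_on and dep.active and len(world.decoys_xy):
        age = dep.age_days(day)
        dxy = world.decoys_xy
        d_all = np.hypot(dxy[:, 0] - xi, dxy[:, 1] - yi)
        for j in np.flatnonzero(d_all <= cfg.detection_radius):
            if lh.is_habituated(pop, i, int(j), day):
                continue
            out.append(CoaCandidate(
                int(j), "decoy", float(d_all[j]), age,
                mate_search_kappa(d_all[j], age, cfg.delta, cfg.gamma,
                                  cfg.min_k)))
    return out


def check_trap_capture(world, i: int, rng: np.random.Generator) -> bool:
    """Capture test against the nearest active trap within 15 m."""
    cfg = world.config
    if not (cfg.traps_on and traps_active(world.doy)):
        return False
    pop = world.pop
    txy = world.traps_xy
    if len(txy) == 0:
        return False
    d = np.hypot(txy[:, 0] - pop.x[i], txy[:, 1] - pop.y[i])
    if d.min() > cfg.encounter_radius_trap:
        return False
    return bool(rng.random() < cfg.capture_prob)


def resolve_encounters(world, i: int, rng: np.random.Generator,
                       selected: CoaCandidate | None = None) -> str | None:
    """Post-step interaction for mate-searching stoat ``i``.

    Under the default selected-COA semantics an interaction happens only
    when ``selected`` (this step's chosen COA) is within 25 m; the partner
    is then the nearest non-habituated opposite-sex stoat or nest in range
    (mates take precedence over decoys), falling back to habituation of
    the selected decoy.  With ``encounter_selected_only=False`` any entity
    within 25 m triggers the interaction.  Returns "mate", "nest",
    "decoy" or None.
    """
    cfg = world.config
    pop = world.pop
    if cfg.encounter_selected_only and (
            selected is None or selected.distance > cfg.encounter_radius_mate):
        return None
    near = [c for c in visible_coas(world, i)
            if c.distance <= cfg.encounter_radius_mate]
    if not near:
        return None
    mates = [c for c in near if c.kind in ("mate", "nest")]
    if mates:
        target = min(mates, key=lambda c: c.distance)
        if target.kind == "nest":
            lh.mate_nest(pop, world.nests, i, target.target_id, rng, cfg,
                         world.day_index)
            return "nest"
        m, f = (i, target.target_id) if pop.male[i] else (target.target_id, i)
        lh.attempt_mating(pop, m, f, world.year, world.doy, rng, cfg,
                          world.day_index)
        return "mate"
    decoy = min(near, key=lambda c: c.distance)
    lh.add_habituation(pop, i, decoy.target_id,
                       world.day_index + cfg.habituation_days)
    return "decoy"
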