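"""Individual states and demographic events.

Stoats are either in HOME_RANGE movement (anchored to a territory centre)
or MATE_SEARCH (roaming for mates during the 15 Sep - 15 Jan oestrous
window).  Reproduction follows the species' delayed placental implantation:
any mating during a season produces a single litter on the 30 October of
the *following* year.  Litters (Poisson, mean 9 kits) stay at the dam's
nest, where unmated female kits form a joint centre of attraction for
males, until all kits disperse on 16 January to uniformly random
territories.  A dam's death (trap or natural) before dispersal kills her
whole litter: kits are modelled as fully dependent.

The population is held as a struct-of-arrays (``Population``) so the
engine's compiled inner loop can operate on flat numpy buffers; the
``Stoat`` record is a read-only per-individual view for inspection and
tests.  Row index doubles as the individual's id (rows are never
compacted within a realisation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import calendar as cal
from .config import ConfigError, SimConfig

# death causes
ALIVE, TRAP_DEATH, NATURAL_DEATH = 0, 1, 2

# habituation ledger: fixed per-individual capacity; codes address decoys
# (0..n_decoys-1), nests (NEST_CODE_BASE + nest row) and stoats
# (STOAT_CODE_BASE + stoat row)
HAB_CAPACITY = 64
NEST_CODE_BASE = 1_000_000
STOAT_CODE_BASE = 2_000_000


@dataclass(frozen=True)
class Stoat:
    """Read-only snapshot of one individual."""

    id: int
    sex: str                 # "F" | "M"
    state: str               # "HOME_RANGE" | "MATE_SEARCH"
    hr_centre: tuple[float, float]
    location: tuple[float, float]
    pregnant: bool
    due_year: int | None
    nursing: bool
    alive: bool


class Population:
    """Struct-of-arrays container for every stoat ever alive in one run."""

    __slots__ = ("male", "x", "y", "hx", "hy", "alive", "ms", "attractive",
                 "pregnant", "due_year", "nursing", "death_cause",
                 "hab_code", "hab_exp", "n")

    def __init__(self, capacity: int = 0):
        self.n = 0
        self._allocate(max(capacity, 16))

    def _allocate(self, capacity: int):
        self.male = np.zeros(capacity, dtype=np.bool_)
        self.x = np.zeros(capacity)
        self.y = np.zeros(capacity)
        self.hx = np.zeros(capacity)
        self.hy = np.zeros(capacity)
        self.alive = np.zeros(capacity, dtype=np.bool_)
        self.ms = np.zeros(capacity, dtype=np.bool_)
        self.attractive = np.zeros(capacity, dtype=np.bool_)
        self.pregnant = np.zeros(capacity, dtype=np.bool_)
        self.due_year = np.full(capacity, -1, dtype=np.int32)
        self.nursing = np.zeros(capacity, dtype=np.bool_)
        self.death_cause = np.zeros(capacity, dtype=np.int8)
        self.hab_code = np.full((capacity, HAB_CAPACITY), -1, dtype=np.int64)
        self.hab_exp = np.full((capacity, HAB_CAPACITY), -1, dtype=np.int64)

    @property
    def capacity(self) -> int:
        return len(self.x)

    def _grow_to(self, need: int):
        if need <= self.capacity:
            return
        new_cap = max(need, self.capacity * 2)
        old, n = self, self.n
        arrays = {}
        for name in self.__slots__:
            if name == "n":
                continue
            arrays[name] = getattr(old, name)
        self._allocate(new_cap)
        for name, arr in arrays.items():
            getattr(self, name)[: len(arr)] = arr
        self.n = n

    def add(self, male: bool, hx: float, hy: float, x: float | None = None,
            y: float | None = None, pregnant: bool = False,
            due_year: int = -1) -> int:
        self._grow_to(self.n + 1)
        i = self.n
        self.male[i] = male
        self.hx[i], self.hy[i] = hx, hy
        self.x[i] = hx if x is None else x
        self.y[i] = hy if y is None else y
        self.alive[i] = True
        self.pregnant[i] = pregnant
        self.due_year[i] = due_year
        self.n += 1
        return i

    def alive_count(self) -> int:
        return int(np.count_nonzero(self.alive[: self.n]))

    def stoat(self, i: int) -> Stoat:
        return Stoat(
            id=i,
            sex="M" if self.male[i] else "F",
            state="MATE_SEARCH" if self.ms[i] else "HOME_RANGE",
            hr_centre=(float(self.hx[i]), float(self.hy[i])),
            location=(float(self.x[i]), float(self.y[i])),
            pregnant=bool(self.pregnant[i]),
            due_year=int(self.due_year[i]) if self.due_year[i] >= 0 else None,
            nursing=bool(self.nursing[i]),
            alive=bool(self.alive[i]),
        )


class NestLedger:
    """Active litters (one per dam), alive only between 30 Oct and 16 Jan."""

    __slots__ = ("dam", "x", "y", "fem", "male", "mated", "fem_pregnant", "alive")

    def __init__(self):
        self.dam = np.zeros(0, dtype=np.int64)
        self.x = np.zeros(0)
        self.y = np.zeros(0)
        self.fem = np.zeros(0, dtype=np.int64)
        self.male = np.zeros(0, dtype=np.int64)
        self.mated = np.zeros(0, dtype=np.bool_)
        self.fem_pregnant = np.zeros(0, dtype=np.int64)
        self.alive = np.zeros(0, dtype=np.bool_)

    def __len__(self):
        return len(self.dam)

    def add(self, dam: int, x: float, y: float, n_fem: int, n_male: int) -> int:
        self.dam = np.append(self.dam, dam)
        self.x = np.append(self.x, x)
        self.y = np.append(self.y, y)
        self.fem = np.append(self.fem, n_fem)
        self.male = np.append(self.male, n_male)
        self.mated = np.append(self.mated, False)
        self.fem_pregnant = np.append(self.fem_pregnant, 0)
        self.alive = np.append(self.alive, True)
        return len(self.dam) - 1

    def clear(self):
        self.__init__()

    def kits_alive(self) -> int:
        live = self.alive
        return int((self.fem[live] + self.male[live]).sum())


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def daily_survival_from_annual(p_annual: float) -> float:
    """Convert an annual survival probability to its daily equivalent,
    p_daily = p_annual ** (1/365)."""
    if not 0.0 < p_annual <= 1.0:
        raise ConfigError("annual survival must lie in (0, 1]")
    return p_annual ** (1.0 / 365.0)


def draw_initial_counts(rng: np.random.Generator,
                        n_range: tuple[int, int] = (6, 12)) -> tuple[int, int, int]:
    """Draw (initialN, nFemales, nMales).

    initialN is uniform on the inclusive range; the female count is
    binomial(initialN, 0.5) redrawn until at least one female remains (a
    female-free remnant population could never be at eradication risk from
    mate-finding failure — it is already doomed — so the model conditions
    on ≥1 female).
    """
    lo, hi = n_range
    initial_n = int(rng.integers(lo, hi + 1))
    n_fem = 0
    while n_fem < 1:
        n_fem = int(rng.binomial(initial_n, 0.5))
    return initial_n, n_fem, initial_n - n_fem


def uniform_points_in_island(island, n: int, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample n points uniformly over the island polygon."""
    minx, miny, maxx, maxy = island.bounds
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(16, 2 * (n - got))
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        ok = island.contains_xy(xs, ys)
        take = min(n - got, int(ok.sum()))
        out[got: got + take, 0] = xs[ok][:take]
        out[got: got + take, 1] = ys[ok][:take]
        got += take
    return out


def init_population(rng: np.random.Generator, config: SimConfig, island,
                    start_year: int = 0) -> Population:
    """Create the remnant population present when decoy management begins.

    Home-range centres are uniform over the island and each stoat starts at
    its centre.  Initial females may carry last season's pregnancy with
    probability ``p_initial_pregnant`` (default 0: trapping is assumed to
    have run through the previous seasons' litters), due on the first
    30 October after the start.
    """
    n_range = (config.initial_n, config.initial_n) \
        if isinstance(config.initial_n, int) else config.initial_n
    _, n_fem, n_male = draw_initial_counts(rng, n_range)
    pop = Population(capacity=64)
    pts = uniform_points_in_island(island, n_fem + n_male, rng)
    for i in range(n_fem + n_male):
        male = i >= n_fem
        pregnant = (not male) and rng.random() < config.p_initial_pregnant
        pop.add(male=male, hx=pts[i, 0], hy=pts[i, 1],
                pregnant=pregnant, due_year=start_year if pregnant else -1)
    return pop


def implantation_due_date(year: int, doy: int) -> tuple[int, int]:
    """Birth date implied by a mating on the given date.

    Delayed implantation: a female fertilised at any point of the oestrous
    season spanning September of year Y to January of year Y+1 gives birth
    on 30 October of year Y+1.
    """
    return cal.season_start_year(year, doy) + 1, cal.BIRTH_DAY


def update_states(pop: Population, doy: int) -> None:
    """Refresh movement state and attractiveness for the current date.

    Inside the oestrous window every male mate-searches; females
    mate-search unless pregnant or nursing.  Pregnant-at-window-start
    females are neither attracted nor attractive; females fertilised during
    the season stop searching but stay attractive, and nursing dams become
    attractive again 10 days after birth.  Outside the window everyone
    reverts to home-range movement.

    Attractiveness flags are managed day-to-day by the engine (they depend
    on mating history); this routine sets the window-boundary baseline.
    """
    n = pop.n
    sl = slice(0, n)
    if cal.in_oestrous_window(doy):
        if doy == cal.OESTRUS_START:
            male = pop.male[sl]
            free_f = ~male & ~pop.pregnant[sl] & ~pop.nursing[sl]
            pop.ms[sl] = (male | free_f) & pop.alive[sl]
            pop.attractive[sl] = pop.ms[sl]
        if doy == cal.DAM_OESTRUS_DAY:
            dams = pop.nursing[sl] & pop.alive[sl]
            pop.attractive[sl] |= dams
    else:
        pop.ms[sl] = False
        pop.attractive[sl] = False


def give_birth(pop: Population, nests: NestLedger, dam: int,
               rng: np.random.Generator, config: SimConfig) -> int:
    """Deliver the litter of a due dam; returns the nest row.

    Litter size is Poisson(meanRecruits = 9) split binomially between the
    sexes.  The dam stops being pregnant, nurses at her current location,
    and will re-enter oestrus 10 days later while keeping home-range
    movement.
    """
    n_kits = int(rng.poisson(config.mean_recruits))
    n_fem = int(rng.binomial(n_kits, 0.5)) if n_kits else 0
    pop.pregnant[dam] = False
    pop.due_year[dam] = -1
    pop.nursing[dam] = True
    pop.ms[dam] = False
    pop.attractive[dam] = False  # oestrus resumes 10 days post-birth
    return nests.add(dam, float(pop.x[dam]), float(pop.y[dam]),
                     n_fem, n_kits - n_fem)


def disperse_nests(pop: Population, nests: NestLedger, island,
                   rng: np.random.Generator, year: int) -> int:
    """On 16 January every surviving kit becomes an independent stoat with a
    uniformly random territory; mated-and-fertilised female kits disperse
    pregnant (due the coming 30 October).  Returns the disperser count."""
    total = 0
    for j in range(len(nests)):
        if not nests.alive[j]:
            continue
        n_fem = int(nests.fem[j])
        n_male = int(nests.male[j])
        n_preg = int(nests.fem_pregnant[j])
        pts = uniform_points_in_island(island, n_fem + n_male, rng)
        for k in range(n_fem + n_male):
            male = k >= n_fem
            pregnant = (not male) and k < n_preg
            pop.add(male=male, hx=pts[k, 0], hy=pts[k, 1],
                    pregnant=pregnant, due_year=year if pregnant else -1)
        dam = int(nests.dam[j])
        pop.nursing[dam] = False
        total += n_fem + n_male
    nests.clear()
    return total


def kill(pop: Population, i: int, cause: int, nests: NestLedger | None = None) -> int:
    """Remove a stoat (and, for a nursing dam, her dependent litter).
    Returns the number of nest kits that died with her."""
    pop.alive[i] = False
    pop.ms[i] = False
    pop.attractive[i] = False
    pop.death_cause[i] = cause
    lost = 0
    if nests is not None and pop.nursing[i]:
        for j in range(len(nests)):
            if nests.alive[j] and nests.dam[j] == i:
                nests.alive[j] = False
                lost += int(nests.fem[j] + nests.male[j])
        pop.nursing[i] = False
    return lost


def apply_natural_mortality(pop: Population, nests: NestLedger, p_daily: float,
                            rng: np.random.Generator) -> tuple[int, int]:
    """End-of-day Bernoulli survival for every free-ranging stoat.

    Kits in nests take no independent draw but die with their dam.
    Returns (adult deaths, dependent kit deaths).
    """
    sl = slice(0, pop.n)
    live = np.flatnonzero(pop.alive[sl])
    if len(live) == 0:
        return 0, 0
    dies = rng.random(len(live)) >= p_daily
    kit_losses = 0
    for i in live[dies]:
        kit_losses += kill(pop, int(i), NATURAL_DEATH, nests)
    return int(dies.sum()), kit_losses


def attempt_mating(pop: Population, male_idx: int, target_idx: int,
                   year: int, doy: int, rng: np.random.Generator,
                   config: SimConfig, day_index: int | None = None) -> bool:
    """Mate a male with an oestrous female; returns True if she conceives.

    Conception is Bernoulli(0.9).  A newly fertilised free-ranging female
    resumes home-range movement and stops seeking mates, but stays
    attractive (males may still mate her) until the window closes.  The
    male is habituated to this female for ``habituation_days`` regardless
    of outcome.
    """
    if not cal.in_oestrous_window(doy):
        raise ValueError("mating outside the oestrous window")
    if not pop.male[male_idx] or pop.male[target_idx]:
        raise ValueError("attempt_mating needs a (male, female) pair")
    if day_index is None:
        day_index = cal.to_day_index(year, doy)
    add_habituation(pop, male_idx, STOAT_CODE_BASE + target_idx,
                    day_index + config.habituation_days)
    if pop.pregnant[target_idx]:
        return False  # already fertilised; extra sires change nothing here
    if rng.random() < config.p_pregnancy:
        due_year, _ = implantation_due_date(year, doy)
        pop.pregnant[target_idx] = True
        pop.due_year[target_idx] = due_year
        pop.ms[target_idx] = False
        return True
    return False


def mate_nest(pop: Population, nests: NestLedger, male_idx: int, nest_idx: int,
              rng: np.random.Generator, config: SimConfig,
              day_index: int) -> int:
    """A male encountering a nest mates every currently unmated female kit;
    each conceives independently with probability 0.9.  Returns the number
    of newly fertilised kits."""
    add_habituation(pop, male_idx, NEST_CODE_BASE + nest_idx,
                    day_index + config.habituation_days)
    if nests.mated[nest_idx]:
        return 0
    n_preg = int(rng.binomial(int(nests.fem[nest_idx]), config.p_pregnancy))
    nests.mated[nest_idx] = True
    nests.fem_pregnant[nest_idx] = n_preg
    return n_preg


def add_habituation(pop: Population, i: int, code: int, expiry_day: int) -> None:
    """Record that stoat i ignores target ``code`` until ``expiry_day``.

    Slots are recycled: an expired slot is reused, otherwise the entry
    closest to expiry is overwritten (the ledger capacity of 64 exceeds any
    realistic number of simultaneous habituations).
    """
    row_c = pop.hab_code[i]
    row_e = pop.hab_exp[i]
    hit = np.flatnonzero(row_c == code)
    if len(hit):
        s = int(hit[0])
        row_e[s] = max(row_e[s], expiry_day)
        return
    s = int(np.argmin(row_e))  # empty (-1) or stalest entry
    row_c[s] = code
    row_e[s] = expiry_day


def is_habituated(pop: Population, i: int, code: int, day_index: int) -> bool:
    row_c = pop.hab_code[i]
    row_e = pop.hab_exp[i]
    for s in range(HAB_CAPACITY):
        if row_c[s] == code and row_e[s] > day_index:
            return True
    return False
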