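"""Simulation configuration.

``SimConfig`` gathers the eight swept biological/management parameters and
every fixed constant of the model in one flat record.  Swept parameter
defaults are the post-hoc scenario values identified by the sensitivity
analysis (the conditions under which Allee effects were probed); the
``sweep_*`` class attributes carry the full sensitivity ranges.

Units: distances in metres, rates per day, probabilities dimensionless.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


class ConfigError(ValueError):
    """A configuration value is outside its valid domain."""


# sensitivity-analysis ranges for the eight swept parameters
SWEEP_RANGES = {
    "initial_n": (6, 12),               # integers, inclusive
    "decoy_spacing": (300.0, 1000.0),   # m, continuous
    "n_deployments": (1, 2),            # per oestrous period
    "alpha": (0.01, 0.1),               # home-range distance decay
    "delta": (0.001, 0.01),             # mate-search distance decay, per m
    "gamma": (0.005, 0.05),             # decoy temporal decay, per day
    "habituation_days": (8, 20),        # days of non-attraction
    "p_daily_survival": (0.9978, 0.9986),
}


@dataclass
class SimConfig:
    """All parameters of one simulation run.

    ``initial_n`` may be a fixed integer or an inclusive (low, high) range
    from which each realisation draws uniformly.
    """

    # --- swept parameters (defaults: post-hoc Allee-scenario values) ---
    initial_n: int | tuple[int, int] = 6
    decoy_spacing: float = 300.0
    n_deployments: int = 2
    alpha: float = 0.02
    delta: float = 0.01
    gamma: float = 0.0051
    habituation_days: int = 19
    p_daily_survival: float = 0.9981

    # --- fixed movement / encounter constants ---
    base_scale: float = 50.0            # Weibull scale, m per 30-min step
    steps_per_night: int = 16           # 8 nocturnal hours in 30-min steps
    detection_radius: float = 2500.0    # COA detection, m
    encounter_radius_mate: float = 25.0
    encounter_radius_trap: float = 15.0
    min_k: float = 0.02                 # minimum-kappa scaling constant
    boundary_max_tries: int = 20

    # --- demography ---
    p_pregnancy: float = 0.9
    mean_recruits: float = 9.0
    # Remnant females carry the previous season's blastocysts (delayed
    # implantation keeps wild females near-continuously pregnant), due on
    # the first 30 October of the run.
    p_initial_pregnant: float = 1.0

    # --- management ---
    capture_prob: float = 0.2
    trap_target_count: int = 2353
    traps_on: bool = True
    decoys_on: bool = True

    # --- horizon / geometry ---
    horizon_years: int = 3
    island_area_km2: float = 208.0
    island_elongation: float = 2.5
    island_seed: int = 7

    # Encounter semantics.  False (default): any non-habituated entity
    # within 25 m triggers an interaction, mates preferred over decoys.
    # True: only the step's *selected* COA within 25 m does, so a stoat
    # locked onto a decoy walks straight past an unselected mate.
    encounter_selected_only: bool = False

    # --- numerics ---
    simulate_idle_nights: bool = False  # step through nights with no possible event
    max_population: int | None = None   # optional early-abort bound (sweeps)

    def __post_init__(self):
        lo, hi = (self.initial_n, self.initial_n) if isinstance(self.initial_n, int) \
            else self.initial_n
        if not 1 <= lo <= hi:
            raise ConfigError("initial_n must be a positive int or (low, high) range")
        if self.n_deployments not in (1, 2):
            raise ConfigError("n_deployments must be 1 or 2")
        for name in ("alpha", "delta", "gamma", "min_k", "base_scale",
                     "detection_radius", "encounter_radius_mate",
                     "encounter_radius_trap"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0.0 <= self.p_daily_survival <= 1.0:
            raise ConfigError("p_daily_survival must lie in [0, 1]")
        if not 0.0 <= self.p_pregnancy <= 1.0:
            raise ConfigError("p_pregnancy must lie in [0, 1]")
        if self.habituation_days < 0:
            raise ConfigError("habituation_days must be non-negative")
        if self.horizon_years < 1:
            raise ConfigError("horizon must be at least one year")

    @property
    def horizon_days(self) -> int:
        return self.horizon_years * 365

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "initial_n" in d and isinstance(d["initial_n"], list):
            d = dict(d, initial_n=tuple(d["initial_n"]))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(d["initial_n"], tuple):
            d["initial_n"] = list(d["initial_n"])
        return d
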