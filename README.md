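# stoatsim

Can deliberately disrupting mate finding help eradicate an invasive
mammal?  `stoatsim` is a spatially explicit individual-based simulator
built around that question for stoats (*Mustela erminea*) on a closed
island: after trapping has ground a population down to a handful of
survivors, artificial reproductive-pheromone decoys are deployed during
the mating season to divert males from females.  If the decoys depress
recruitment enough, the population slips below an Allee threshold and
demographic stochasticity finishes the job.  The package is aimed at
quantitative ecologists and eradication programme designers who want to
explore when such a component (mate-finding) Allee effect exists and when
it becomes demographic.

## The model in brief

Stoats move in 16 nightly 30-minute steps.  Step lengths are
Weibull(shape = 1, scale = 50 m); bearings are von Mises around the
current centre of attraction (COA) with concentration κ:

* home-range mode: κ = max(0, α·ln d), d the distance to the territory
  centre — the further out, the stronger the pull home;
* mate-search mode (15 Sep – 15 Jan): candidate COAs are opposite-sex
  receptive stoats, nests with unmated female kits, and pheromone decoys
  within 2.5 km, weighted κ_c = (1/minK)·e^(−δ·d_c)·e^(−γ·a_c) (a_c =
  days since decoy deployment); one is drawn per step with probability
  κ_c/Σκ.

An encounter within 25 m mates a female (conception 0.9, mates preferred
over decoys) or habituates the stoat to a decoy for `habituationDays`.
Delayed placental implantation turns any mating this season into a litter
(Poisson mean 9) next 30 October; kits disperse on 16 January.  Daily
survival is P(annual)^(1/365); 2353 lattice traps kill with probability
0.2 within 15 m during three 14-day sessions a year.  Eradication is the
population reaching zero within the 3-year horizon.

On top of the simulator sit the two published experiments: the
four-scenario Allee test (none / traps / decoys / traps + decoys, 400
realisations each) and a 5000-iteration uniform sensitivity sweep of
eight parameters, analysed by Bayesian logistic regression (componentwise
Metropolis, Normal(0, 10) priors) with DIC model comparison.

See `docs/methods.md` for the full model description and the package's
numerical choices.

## Worked example

`examples/` holds one short script per capability.  The scenario
experiment (`examples/03_scenario_experiment.py`, 60 replicates for
speed):

```text
P(eradication | none      ) = 0.067 +/- 0.032
P(eradication | trap_only ) = 0.783 +/- 0.053
P(eradication | decoy_only) = 0.033 +/- 0.023
P(eradication | trap_decoy) = 0.683 +/- 0.060

component Allee effect (trap+decoy > trap): False
demographic Allee effect (decoy > none):     False
```

Read: with no intervention almost every remnant population of six
recovers (the females arrive pregnant) and trapping eradicates about
three times in four.  Sixty replicates are too few to resolve the small
decoy effects — at the full 400 paired replicates the decoy-only arm
rises above no-intervention (0.050 vs 0.040), the demographic
Allee-effect signal.  The synthetic lattice trap network is more lethal
than the real, terrain-constrained one, so the trapping arms saturate
near 0.75 and leave decoys little measurable headroom there (see
`docs/methods.md`).

The movement-kernel calibration (`examples/01_home_range_kernel.py`):

```text
alpha =  0.02  ->  95% MCP home range =   8.35 km^2
alpha =  0.05  ->  95% MCP home range =   1.82 km^2
alpha =  0.10  ->  95% MCP home range =   0.59 km^2
```

## Command line

A thin CLI wraps the library: `stoatsim simulate`, `stoatsim scenarios`,
`stoatsim sensitivity`, `stoatsim fit` (see `--help` on each).  Custom
islands load from GeoJSON/WKT in projected metres; trap layouts from
`id,x,y` CSV.
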