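# Model and methods

`stoatsim` is a spatially explicit individual-based model built to ask a
management question: can artificial reproductive-pheromone decoys disrupt
mate finding in a remnant stoat (*Mustela erminea*) population strongly
enough to elicit component and demographic Allee effects, and thereby help
finish an island eradication that trapping alone cannot?  This note
documents the model, its parameters, the numerical choices, and what the
synthetic experiments do and do not show.

## The simulated system

A closed population of stoats on an island of 208 km² (no immigration, no
emigration).  Habitat and topography are not modelled; the landscape is a
bare planar polygon in metre coordinates.  Time advances in 365-day years
with fixed seasonal anchors:

| event | date |
|---|---|
| oestrous (mating) window | 15 Sep – 15 Jan |
| decoy deployment (refresh) | 15 Sep (15 Nov) |
| births | 30 Oct |
| dam returns to oestrus | 9 Nov (birth + 10 d) |
| kit dispersal | 16 Jan |
| trap sessions (14 d baited) | from 20 Jan, 20 Jul, 20 Nov |

Simulations start on 15 September of year 0 — the moment decoy management
begins against a trapped-down remnant of 6–12 animals — and run for three
years or until extinction.

## Movement

Stoats are nocturnal: each simulated night consists of 16 sequential
30-minute steps.  A step is a draw of a length and a compass bearing
(0 = north, east positive, domain (−π, π]):

* length ~ Weibull(shape 1, scale), i.e. exponential with mean `scale`
  (50 m outside of close approaches);
* bearing ~ von Mises(μ, κ) where μ points at the current centre of
  attraction (COA) and κ sets how tightly the step tracks it; κ = 0 is a
  uniformly random direction.

**Home-range mode** (everyone outside the mating window; pregnant and
nursing females inside it): the COA is the territory centre and
κ = max(0, α·ln d) at distance d metres.  The pull grows with distance and
vanishes within a metre of the centre, producing a stationary range.  The
printed formula for this gain is typographically ambiguous; we adopt
α·ln d (natural log) because it makes α a plain multiplicative gain and,
at α = 0.05 with 50 m steps, yields a 95% minimum-convex-polygon range of
≈ 1.9 km², consistent with the ~2.5 km² field estimate used to calibrate
the kernel (the alternative reading (ln d)^α concentrates the walk far too
tightly).  α is swept over [0.01, 0.1].

**Mate-search mode** (males, and non-pregnant females, during the window):
candidate COAs are all opposite-sex receptive stoats, nests holding
unmated female kits (for males), and active decoys within a 2.5 km
detection radius, excluding targets under habituation.  Each candidate c
gets a weight

    κ_c = (1/minK) · exp(−δ·d_c) · exp(−γ·a_c)

with d_c the distance, a_c the days since the decoy's deployment (0 for
live animals), δ ∈ [0.001, 0.01] the scent distance decay per metre and
γ ∈ [0.005, 0.05] the decoy's temporal decay per day.  One COA is selected
per step by a multinomial draw with probabilities κ_c/Σκ_c (the 1/minK
factor cancels there; it only scales the bearing concentration).  With no
candidate in range the bearing is uniform.  Within 50 m of the selected
COA the step-length scale shrinks to half the remaining distance, so the
walker converges instead of overshooting.

`minK` is not given by the source material; it is a configuration constant
with default 0.02, making κ = 50 (a hard lock-on) at zero distance.

**Boundary.**  The island is closed: a step that would land in the sea is
redrawn (bearing and length) up to 20 times, after which the animal stays
put for that half hour.  Rejection keeps the stationary behaviour near the
coast unbiased, unlike truncating steps at the shoreline.

## Encounters and mating

At the end of each step a mate-searching stoat within 25 m of a COA may
interact.  Two semantics are implemented (`encounter_selected_only`):

* **opportunistic (default):** any non-habituated entity within 25 m
  triggers an interaction, a stoat of the opposite sex or a nest taking
  precedence over a decoy.  Under this reading dense decoy grids pin and
  distract searchers, and habituation accumulates quickly across the
  local grid; measured over the no-trapping scenario pair, decoys
  suppress conceptions by roughly a fifth and raise the eradication
  probability — the intended mate-finding disruption.
* **selected-COA:** an interaction occurs only when the step's *selected*
  COA is within 25 m (partner still chosen mate-first among everything in
  range).  Literal to the "selected COA" phrasing, but because a stoat
  then habituates only to decoys it actually reaches, the grid stays
  attractive and ferries searchers decoy-to-decoy across the island:
  measured conceptions *rise* at low density and the disruption inverts.
  Retained as an option for exactly that comparison.

An encountered female conceives with probability 0.9; if she conceives she
reverts to home-range movement and stops searching, but remains receptive
(males may still select and mate her) until 15 January.  The male is
habituated to that female — and any stoat to an encountered decoy — for
`habituationDays` (8–20 d, post-hoc 19 d): the target is simply invisible
to him until the ledger entry expires.  A male encountering a nest mates
every not-yet-mated female kit in it at the same 0.9 conception
probability; the nest then stops attracting males.

## Reproduction and mortality

Delayed placental implantation governs all breeding: any female fertilised
during the season that opens in September of year Y gives birth on
30 October of year Y+1.  Litters are Poisson(9) split binomially between
the sexes; kits stay at the nest (no movement, no survival draws) until
all disperse on 16 January to uniformly random territories.  Female kits
mated in the nest disperse pregnant.  A dam's death before dispersal —
by trap *or* natural causes — kills her litter; kits are modelled as fully
dependent (the source states this for trapping; we extend it to natural
death because unattended neonates cannot survive).

Initial females enter the model pregnant (config `p_initial_pregnant`,
default 1.0), due the first 30 October.  This follows the species'
biology — delayed implantation keeps wild females near-continuously
pregnant, and the model explicitly handles females "pregnant on
15 September" from day one.  The no-intervention eradication probability
is diagnostic here: with pregnant survivors it sits near the few-percent
level reported for demographic stochasticity alone; with virgin survivors
it rises an order of magnitude, because year-one recruitment then depends
entirely on rare low-density mate finding.

Every free-ranging stoat survives each day with P(daily) =
P(annual)^(1/365); the swept range 0.9978–0.9986 corresponds to annual
survival 0.45–0.61.  Traps kill: during a baited session, a stoat within
15 m of its nearest trap at the end of any step is captured with
probability 0.2.  The trap network is a square lattice whose spacing is
solved so the count matches the real network's 2353 traps; a uniform
lattice covers the island more evenly than the real, terrain-constrained
layout, so trapping here is somewhat *more* lethal than in the field.

## Experiments

**Scenarios.**  Four management arms at the post-hoc parameter set
(initialN = 6, spacing 300 m, 2 deployments, α = 0.02, δ = 0.01,
γ = 0.0051, habituation 19 d, P(daily) = 0.9981): nothing, traps only,
decoys only, traps + decoys; 400 realisations each, eradication
probability = eradications/400.  Replicate r of every arm shares a seed
(common random numbers), sharpening paired comparisons without biasing
the marginals.  Inference: component (mate-finding) Allee effect if
P(trap+decoy) > P(trap only); demographic Allee effect if
P(decoy only) > P(none).

**Sensitivity sweep.**  Each iteration draws the eight swept parameters
uniformly from their ranges (spacing continuous on [300, 1000];
deployments on {1, 2}; initialN integer on [6, 12]; habituation integer on
[8, 20]), runs one realisation with traps and decoys active, and records
the binary outcome.  The full design is 5000 iterations; the test suite
runs 1000, which is ample for the sign pattern of the dominant effects.
Runs whose population exceeds 500 are scored as failures without further
simulation — eradication from 500 animals within the remaining horizon is
unreachable, and the bound only ever triggers in sweep corners (high
survival, sparse decoys).

**Regression.**  Eradication ~ Bernoulli(p), logit(p) = β0 + Σ β_z Z_z on
covariates standardised by sample mean and (n−1) sd; priors
Normal(0, variance 10) on every coefficient.  Sampling is componentwise
random-walk Metropolis with proposal scales adapted during a 5000-sweep
burn-in towards 30–40% acceptance, then 3000 samples retained at thinning
20 (test fits use shorter chains).  Six candidate covariate subsets are
compared by DIC = D̄ + pD, pD = D̄ − D(β̄).

## Numerical choices

* One numpy `Generator` per realisation; every draw (movement, demographic,
  order shuffling) flows through it, so runs are bit-reproducible given
  the seed.  Experiment drivers derive child seeds as SeedSequence
  [master, replicate].
* The nightly loop is a numba kernel over flat arrays; decoys and traps
  are pre-binned into uniform-grid neighbour lists, so per-step candidate
  scans touch only points within one detection radius.
* Nights on which movement can have no observable effect — outside the
  mating window and outside active trap sessions — are skipped; only the
  daily survival draw runs.  Home-range movement is stationary around the
  territory centre, so the stored position remains a valid sample of
  where the animal would be.  `simulate_idle_nights=True` restores full
  stepping for trajectory work.
* Von Mises draws use the Best–Fisher rejection sampler; below κ = 1e−6
  the distribution is numerically uniform and is sampled as such.
* Stoats act in freshly shuffled order each step, so simultaneous
  encounters (several males reaching one female) resolve in random order
  and all succeed, and no animal systematically moves first.
* The synthetic island is a smoothed star polygon (elongated ellipse with
  low-frequency radial noise, aspect ratio 2.5), rescaled to exactly
  208 km²; traps and decoys are axis-aligned lattices clipped to it.
  Geometry is deterministic given its seed and shared across realisations.

## What the synthetic setting does not show

The island, trap layout and decoy grids stand in for a real fiordland
island and its terrain-constrained trap network.  Uniform lattice traps
kill harder than the real network, so absolute eradication probabilities
in the trapping arms overshoot the field-calibrated values and compress
the headroom in which decoys can add effect; the decoy-free arms
(no intervention, decoys only) are insensitive to trap geometry and land
on the reported scale.  Real habitat heterogeneity, swimming between
islands, age structure beyond kit/adult, trap saturation and decoy cost
are all out of scope.
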