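# Methods

## Diel time expansion

The base network is replicated into N copies, one per time interval of a
24-h cycle (N must divide 24; 24, 12, 6 and 4 are the supported
discretisations, i.e. 1/2/4/6-h intervals). Interval t is at steady state
for every metabolite; for each *storable* a non-negative linker flux L[s,t]
(umol m-2 s-1) moves the amount accumulated during interval t into interval
t+1 mod N, so a linker flux of 1 umol m-2 s-1 over a 1-h interval transfers
3.6 mmol m-2. The wrap-around linker closes the cycle, which makes the
solution a periodic diel orbit: summed over the cycle, every storable's
in- and out-flows cancel identically.

Storables are starch in the plastid and, in the vacuole: glucose, fructose,
sucrose, malate, citrate, isocitrate, the network's amino acids and nitrate.
Starch accumulates freely; the vacuolar pool is capacity-limited (below).

## Environment

Temperature and relative humidity follow 24-h-periodic skewed sine curves:
the clock is phase-warped linearly between the two anchors (minimum,
maximum), and position along each arc is additionally warped as u -> u^skew.
Anchors default to the temperature minimum 1 h before sunrise and the
maximum at 15:00, with humidity anti-phased. The default skew of 0.5
reproduces the asymmetry of measured diel temperature records — rapid
post-sunrise warming, slow pre-dawn cooling; a symmetric sine (skew = 1)
leaves the first post-sunrise hours as cool as deep night, which
exaggerates early-morning stomatal opening. Light is a Gaussian centred on
solar noon whose width is fixed by requiring the intensity to equal the
light compensation point (30 umol m-2 s-1, default) exactly at
noon +/- daylength/2; values below the compensation point are darkness.
Profiles are sampled at interval midpoints; an interval is "day" iff its
light reaches the compensation point.

Reference conditions (a summer day in a temperate climate): T 20-30 degC,
RH 0.4-0.8, peak light 250 umol m-2 s-1, 12-h photoperiod, N = 24.

## Gas exchange

Water loss is tied to CO2 demand by a linearized stomatal diffusion model:

    r(T, h) = diff_ratio * (e_sat(T)/P) * (1 - h) / (c_atm * (1 - ci_ratio))

in mol H2O per mol CO2, with diff_ratio = 1.6 (H2O:CO2 diffusivity),
P = 101.325 kPa, c_atm = 400 umol mol-1, ci_ratio = 0.7, and e_sat the Buck
equation 0.61121 exp((18.678 - T/234.5) (T/(257.14 + T))) kPa (accurate to
<0.1% over 0-50 degC; swappable in `GasExchangeParams`). Daily water loss is
the time-weighted sum of r_t times the CO2-uptake flux. Only net uptake
carries a transpiration cost; respiratory efflux is a separate free
reaction, since CO2 release does not require open stomata in proportion to
flux the way uptake does. Stomatal regulation, boundary-layer and mesophyll
conductance, and leaf energy balance are outside the model: uptake patterns
are emergent properties of the optimization.

## Diel constraints

Defaults, applied per interval:

| constraint | value |
|---|---|
| phloem export, day:night per-hour rate | 3:1 |
| nitrate uptake, day:night | 3:2 |
| maintenance, day:night | 3:1 |
| maintenance ATP:NADPH | 3:1 |
| Rubisco carboxylation:oxygenation (equality, day only) | 3:1 |
| Rubisco at night | inactive (bounds 0) |
| stomatal CO2 uptake | <= 15 umol m-2 s-1 |
| light compensation point | 30 umol m-2 s-1 |

Day/night rate ratios are implemented as equality couplings — all day
intervals share one per-hour rate, all night intervals another, and the two
rates stand in the stated ratio — because a per-interval ratio would be
ill-defined. Daytime ATP maintenance is k times the mean daytime light
intensity (k = 0.008 flux units per unit light, chosen to put maintenance at
a few percent of the leaf's ATP budget); night is a third of that and NADPH
maintenance a third of the ATP value in each period.

## Vacuolar storage capacity

For every interval boundary, the summed vacuolar solute amount carried
across it (linker flux x interval length, uniform 1 mol capacity per mol
stored; per-metabolite weights and the inclusion of nitrate are
config-exposed, since osmotic weighting is not identifiable here) must not
exceed the capacity. The C3 default of 0.1 mol m-2 is a calibration, not a
measurement: `scripts/calibrate_vacuole.py` scans candidates and the default
is the smallest at which the CAM-anatomy variant (3.1x the C3 capacity, the
morphological ratio between average CAM and C3 leaves) saves more than half
of its water at 80% of maximum phloem output while storing overnight
carboxylic-acid pools of ~150 mmol m-2, the order measured in CAM leaves.
Capacity 0 disables vacuolar carry-over entirely (starch unaffected); +inf
or None removes the constraint (the "unlimited storage" variant).

## Objectives and solvers

The lexicographic stack is:

1. **max phloem output** — LP (HiGHS via scipy.optimize.linprog);
2. **min water loss** s.t. phloem >= floor — LP;
3. **min sum(v^2)** over all step reactions and linkers, with the earlier
   objectives pinned to within a relative tolerance of 1e-6 — the L2
   selection among alternative optima, preferring fluxes spread evenly over
   time (a proxy for enzyme provisioning cost).

Stage 3 solves the exact QP with OSQP on small instances (<= 800 variables).
On full diel models (~2900 variables) ADMM converges too slowly at useful
tolerances, so the default engine is a piecewise-linear convex surrogate of
the quadratic: each variable is split into signed segments between fixed
breakpoints with secant slopes b_k + b_{k+1}, which agrees with x^2 at every
breakpoint and is solved as an LP. Either engine's point is then projected
back onto the constraint polytope by an L1-distance LP ("polish"), so final
solutions satisfy steady state to LP precision; the acceptance checks assert
residuals below 1e-9 and solutions typically reach 1e-13. Reported solution
quantities: daily phloem output and CO2 uptake integrate the respective
fluxes; the water total is always recomputed from the uptake profile and the
closed-form coefficients, independent of solver auxiliaries; the L1 flux sum
is the sum of |v| over step reactions and linkers (meaningful after stage 3 —
LP-only solutions can carry large degenerate cycles). Fluxes below 1e-7 are
zeroed in reports, never in solutions.

Pareto frontiers lower the phloem floor from 100% of the maximum in 5%
steps (default floor 20%); each point is a stage-2 (optionally stage-3)
solution, and per-point solver failures are recorded without aborting the
scan.

## Scenarios

* `ICDH_rev` (base): mitochondrial ICDH reversible, so it can carboxylate
  2-oxoglutarate to isocitrate at night (the isocitrate-citrate-Pro-2OG
  cycle).
* `ICDH_irrev`: mitochondrial ICDH clamped to its conventional forward
  direction; the cytosolic NADP isoform keeps its base bounds.
* `ICDH_irrev_Cit_night`: additionally blocks vacuolar (iso)citrate *import*
  during day intervals (export stays open), removing the daytime
  malate-for-citrate exchange.

Variants within a family are solved at one common phloem floor (80% of the
reference CAM model's maximum by default), which makes the
constraint-relaxation ordering water_rev <= water_irrev <= water_cit exact.
Environment grids scan T_max x RH_min per (light, photoperiod) combination
with T_min = T_max - 10 degC and RH_max = min(1, RH_min + 0.4); each cell
records the C3-anatomy water loss at 100% productivity (the water-saving
reference) and the rev/irrev CAM losses at the scan fraction.

## Reporting

CO2 and ATP budgets sum each reaction's signed stoichiometric contribution
to the species class (CO2 includes bicarbonate) per interval; rows are kept
when the magnitude exceeds 0.5 umol m-2 s-1 (configurable) at one or more
intervals, and exchange reactions are included so each budget closes to
zero. ATP turnover is total production summed over the day in flux units.
Storage profiles convert linker fluxes to stored mmol m-2; the significance
flag uses the same 0.5 flux-equivalent threshold.

CAM phases are labelled per interval from the uptake profile and light
state: dark intervals are phase I (with a separate flag for whether
nocturnal uptake actually occurs), lit intervals without uptake are phase
III, and lit uptake runs are phase II when they touch dawn, IV when they
touch dusk, split at solar noon when they span the whole photoperiod, and
assigned by their position relative to noon when isolated.

## The synthetic core network

`build_toy_core` emulates the compartment structure and route repertoire of
a curated plant core model at ~1/10 scale: lumped light reactions (linear
electron flow 8 photons -> 3 ATP + 2 NADPH, cyclic 2 photons -> 1 ATP),
Rubisco carboxylase/oxygenase on a lumped CBB cycle, two-carbon
photorespiration through glycine decarboxylase with ammonia refixation,
starch and sucrose turnover, glycolysis, PEPC with carbonic anhydrase, a
lumped TCA cycle with reversible mitochondrial NAD-ICDH and aconitase in
both mitochondrion and cytosol, peroxisomal citrate synthase and malate
dehydrogenase, NAD/NADP malic enzymes, the proline cycle (P5CS, P5CR,
ProDH, P5CDH, GDH), nitrate assimilation into a phloem amino-acid pool,
vacuolar transporters for all storables, maintenance sinks, and a
fixed-composition phloem export (80:20 sucrose:amino acid by default; the
analysis is robust to this composition). Bookkeeping balances carbon,
nitrogen, phosphate groups, redox/CoA moieties and photons in every
non-exchange reaction — verified by an LP that finds a strictly positive
conserved metabolite weighting — but protons, oxygen and water are not
tracked; full charge balance is the domain of curated SBML models read
through `read_sbml`.

What the synthetic network does *not* emulate: realistic absolute scale
(its daily totals are ~1/10 of a crop leaf's, so comparisons with measured
leaves are meaningful for ratios — water per CO2, percent savings, phase
patterns — not absolute fluxes), isoform multiplicity, gene-protein-reaction
rules, thermodynamic constraints beyond the scenario bounds, and full
osmotic/charge accounting in the vacuole. Passing tests therefore establish
the framework's behaviour (orderings, phase structure, environment trends)
on a faithful miniature, not quantitative predictions for any particular
species.

## Problem sizes and runtimes

A 24-interval expansion of the synthetic network has ~2500 reaction-interval
variables plus ~300 linkers; one LP solves in ~0.2 s and a full three-stage
solve in ~5 s on one CPU. The shipped analyses use 24 intervals, Pareto
steps of 5-10%, and small environment sub-grids; the full published-style
grid (20 T values x 7 RH values x 12 light/photoperiod combinations, three
solves per cell) is supported through the same API and CLI but is sized in
hours, not minutes.

## Known limitations

The anticipatory optimum concentrates nocturnal uptake into the cheapest
pre-dawn hours rather than spreading it across the night as real CAM plants
do; there is no kinetic or regulatory layer; the Rubisco
carboxylation:oxygenation ratio is fixed rather than CO2-dependent, so the
benefit of carbon concentration behind closed stomata is not credited;
enzyme cost enters only through the flux-sum objective after water, never as
a competing Pareto axis.
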