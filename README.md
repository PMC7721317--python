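# dielfba

Time-resolved, environment-coupled diel flux balance analysis of leaf
metabolism: a framework for studying the trade-off between photosynthetic
productivity and transpirational water loss in C3 and CAM
(Crassulacean acid metabolism) leaves.

## The problem

CAM plants fix CO2 at night with phospho*enol*pyruvate carboxylase (PEPC),
store it in the vacuole as carboxylic acids, and release it behind closed
stomata during the hot, dry daytime for refixation by Rubisco. Because the
vapour-pressure gradient that drives transpiration is far smaller at night,
this temporal separation saves large amounts of water per mole of carbon
fixed. Whether (and where) engineering CAM-like metabolism into C3 crops pays
off depends quantitatively on leaf anatomy (vacuolar storage capacity), on
the environment (temperature, humidity, light, photoperiod), and on which
nocturnal carboxylation routes the network can recruit — including, besides
PEPC, mitochondrial isocitrate dehydrogenase (ICDH) running in reverse as a
2-oxoglutarate carboxylase fed by a proline/glutamate shuttle.

`dielfba` is aimed at plant systems biologists who want to pose these
questions as constraint-based optimization problems.

## The model

A compartmented metabolic network (cytosol, plastid, mitochondrion,
peroxisome, vacuole) is replicated into N time intervals covering 24 h
(N = 24 by default). Within each interval t the network is at steady state,

    S v_t + L_{t-1} - L_t = 0,

where the non-negative *linker* fluxes L_t transfer storable metabolites
(starch in the plastid; sugars, malate, citrate, isocitrate, amino acids and
nitrate in the vacuole) from interval t to t+1; interval N-1 feeds interval 0,
closing the diel cycle. Diel physiology enters as per-interval constraints:
photon uptake bounded by a Gaussian light curve, Rubisco active only in
daylight at a fixed 3:1 carboxylation:oxygenation ratio, 3:1 day:night phloem
export and maintenance, 3:2 day:night nitrate uptake, a 15 umol m-2 s-1 cap
on stomatal CO2 uptake, and an upper bound on the total vacuolar solute
amount carried across any interval boundary (3.1-fold higher for CAM than C3
leaf anatomy).

Stomatal gas exchange is a linearized diffusion model: the water cost of one
mole of CO2 at temperature T and relative humidity h is

    r(T, h) = 1.6 * (e_sat(T)/P) * (1 - h) / (c_a * (1 - c_i/c_a)),

with e_sat the saturation vapour pressure (Buck equation), P atmospheric
pressure, c_a = 400 umol mol-1 the atmospheric CO2 mole fraction and
c_i/c_a = 0.7 the internal:atmospheric CO2 ratio.

Solutions come from a lexicographic stack: (1) maximize daily phloem output
(LP); (2) minimize daily water loss at a fixed phloem floor (LP); (3)
minimize the metabolic flux sum as an L2 norm (QP) to select, among
alternative optima, the distribution with the least temporal variation — a
proxy for enzyme cost. Pareto frontiers are scanned by lowering the phloem
floor in 5% steps.

The package ships a synthetic ~100-reaction plant core network
(`build_toy_core`) with every pathway the analysis traverses, so the full
pipeline runs without downloads; curated genome-scale models can be read
from SBML (`read_sbml`) with configurable role-tag patterns.

## Worked example

```python
from dielfba import (DielConstraintSet, apply_vacuole_capacity, build_toy_core,
                     couple_water_loss, expand_diel, make_profile,
                     maximize_phloem, minimize_water)

net = build_toy_core()                   # synthetic plant core network
env = make_profile()                     # 30 degC / RH 0.4 summer day, 12 h light
cs = DielConstraintSet()

def model(capacity):
    m = expand_diel(net, env, cs)        # 24 coupled copies + linkers
    couple_water_loss(m)                 # attach the gas-exchange model
    return apply_vacuole_capacity(m, capacity)

c3, cam = model(cs.vacuole_capacity_c3), model(cs.vacuole_capacity_cam)
p_max = maximize_phloem(c3, flux_min=False).phloem_output
ref = minimize_water(c3, p_max, flux_min=False)
print(f"C3 at 100%: phloem {ref.phloem_output:.4f} mol m-2 d-1, "
      f"water {ref.water_total:.1f} mol m-2 d-1, "
      f"{ref.water_total / ref.co2_total:.1f} mol H2O per mol CO2")

p_cam = maximize_phloem(cam, flux_min=False).phloem_output
w100 = minimize_water(cam, p_cam, flux_min=False).water_total
w80 = minimize_water(cam, 0.8 * p_cam, flux_min=False).water_total
print(f"CAM anatomy at 80%: water {w80:.1f} vs {w100:.1f} mol m-2 d-1 "
      f"({100 * (1 - w80 / w100):.1f}% saved)")
```

prints

```
C3 at 100%: phloem 0.0421 mol m-2 d-1, water 113.8 mol m-2 d-1, 255.3 mol H2O per mol CO2
CAM anatomy at 80%: water 42.0 vs 86.2 mol m-2 d-1 (51.3% saved)
```

The C3 leaf spends ~255 mol of water per mol of CO2 fixed — the expected
order for a temperate summer day — while the CAM-anatomy leaf gives up 20%
of its productivity to cut water loss by more than half. Inspecting the 80%
CAM solution (`detect_phases`, `co2_budget`, `linker_profiles`) shows all
four canonical CAM phases, nocturnal fixation shared between PEPC and
reverse mitochondrial ICDH, and overnight (iso)citrate + proline storage.

A `dielfba` command-line tool wraps the same pipeline
(`dielfba solve|pareto|scan|report`, see `--help`).

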