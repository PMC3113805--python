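# allomax

Predicting the maximum sustainable tree height of a site from its long-term
mean climate, by combining allometric scaling laws with a canopy energy
budget and a precipitation water budget.

## The problem and who this is for

The tallest tree a location can support is a compact summary of its forest:
it co-varies with standing biomass, size structure and resource use.
`allomax` is a steady-state, analytic alternative to demographic forest
simulators, for ecophysiologists and earth-system modellers who want the
climate envelope of tree stature — and trait–climate predictions derived
from it — without simulating stand dynamics.

## The model

An idealized average tree has every dimension tied to its height *h* by
power laws (trunk diameter, crown radius and depth, root extent, leaf
count).  Three water flows are compared as functions of *h*:

- **Q0(h)** — basal metabolic requirement, a two-regime power law of trunk
  diameter `Q0 = β·D^η`, with `h = γ·D^(2/3)`;
- **Qevap(h, env)** — the transpiration stream the environment drives,
  obtained by solving the canopy energy budget
  `R_abs = A_L·ε·σ·T_L⁴ + A_H·c_p·g_Ha·(T_L − T_air) + A_E·λ·g_v·(e_s(T_L) − e_a)/p`
  for canopy temperature T_L and converting the evaporative molar flux E to
  litres per day;
- **Qp(h, env)** — supply from rain intercepted over the root footprint,
  `Qp = η_root·P·π·r_root(h)²`.

A tree is viable while `Q0(h) ≤ Qevap(h) ≤ Qp(h)`; the predicted maximum
height is where the viable region attached to the seedling scale ends, and
the curve Qevap crosses there tells you whether the site is metabolically
(energy) limited or water limited.  The same machinery yields the
height–albedo curve `ρ_deep + (ρ_soil − ρ_deep)·e^(−k·LAI(h))`, the
stomatal density and leaf size that maximize the height bound in a given
climate, and the response of heights to uniform temperature shifts.  See
`docs/methods.md` for assumptions, calibration defaults and limitations.

## Worked example

```python
import numpy as np
from allomax import (Environment, default_config, max_height, flow_curves,
                     canopy_albedo, optimal_stomatal_density)

cfg, traits, params = default_config()   # shipped calibration
env = Environment(precipitation=1.46, air_temperature=17.7,
                  relative_humidity=0.54, wind_speed=3.2,
                  solar_radiation=230.0, site_id="piedmont")

res = max_height(env, traits, params, cfg, mode="both")
print(f"h* = {res.max_height:.2f} m, binding = {res.binding_constraint}")

fc = flow_curves(env, traits, params, cfg, np.array([10.0, 50.0, res.max_height]))
for h, q0, qe, qp in zip(fc.heights, fc.q_required, fc.q_evaporative, fc.q_available):
    print(f"h={h:6.2f}  Q0={q0:8.2f}  Qevap={qe:8.2f}  Qp={qp:8.2f}")
```

prints

```
h* = 105.41 m, binding = water
h= 10.00  Q0=    0.39  Qevap=   19.39  Qp=  124.98
h= 50.00  Q0=   61.77  Qevap=  909.95  Qp= 1641.36
h=105.41  Q0=  647.36  Qevap= 5413.61  Qp= 5413.55
```

At this warm, moderately dry site the tree is water-limited: at the
predicted 105 m the evaporative flow (5414 L/day) has risen to meet the
precipitation supply, while the basal requirement (647 L/day) is still
comfortably covered — growing any taller would overdraw the water budget.
Continuing,

```python
print(canopy_albedo(2.0, traits, cfg), canopy_albedo(60.0, traits, cfg))
opt = optimal_stomatal_density(env, traits, params, cfg, (20.0, 600.0))
print(opt.value, opt.h_max)
```

gives albedo 0.240 for a 2 m sapling against 0.171 for a 60 m canopy (the
crown darkens toward the deep-canopy reflectance as it closes), and an
optimal stomatal density of 30.7 mm⁻² — much lower than the default
200 mm⁻², because shedding conductance is how a tree at a dry site stays
inside its water budget (the bound rises to the 150 m search ceiling).

## Command line

```sh
allomax synth --n-sites 20 --out sites.csv          # synthetic climatologies
allomax predict --env sites.csv --mode both --out heights.csv
allomax curves --env sites.csv --site-id site003 --out curves.csv
allomax shift --env sites.csv --delta-t 2 --out shift.csv
allomax sensitivity --env sites.csv --law root_radius --out sens.csv
allomax optimize-trait stomatal-density --env sites.csv --bounds 20,600 --out opt.csv
```

Every prediction run writes a `*.runlog.json` containing the fully resolved
configuration.  Site tables are CSV with columns `site_id, precip_m_yr,
tair_c, rh_frac, wind_m_s, solar_w_m2, pressure_kpa`; a custom calibration
is a TOML file following `src/allomax/data/default_config.toml`.

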