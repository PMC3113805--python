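# Methods

## The model

`allomax` computes, for one idealized "average" tree placed in one site's
long-term-mean climate, three water flow rates as functions of tree height
*h* and finds the tallest height at which they are mutually compatible:

- **Q0(h)** — the basal metabolic flow requirement: the minimum internal
  water flux needed to keep a tree of that size alive.  It is a two-regime
  power law in trunk diameter *D* (L/day from cm), with diameter obtained
  from height by inverting the height–diameter law *h = γ·D^(2/3)*
  (elastic-similarity exponent for large trees).
- **Qevap(h, env)** — the evaporative flow the environment actually drives
  through the tree.  Trees are passive solar pumps: the transpiration stream
  equals the evaporation rate set by the canopy energy budget (below).
- **Qp(h, env)** — the supply: precipitation intercepted by the flat disc of
  ground above the root system, times a root absorption efficiency η:
  `Qp = η · P · π · r_root(h)²`, converted from m³/yr to L/day (365.25-day
  year).  Runoff, pooling, storage and snow are deliberately excluded.

A height is viable when `Q0(h) ≤ Qevap(h) ≤ Qp(h)`.  The maximum height is
the upper edge of the viable region that contains the seedling scale — a
tree must grow through every intermediate size, so disconnected viable
islands at larger heights are reported as diagnostics but never used.  The
solver scans 400 log-spaced heights in [0.5 m, 150 m] and bisects the
bracketing interval to 0.01 m.  Which curve Qevap crosses at the edge is
recorded as the binding constraint: `metabolic` (Qevap falls to Q0 — humid,
low-energy sites), `water` (Qevap exceeds Qp — bright, dry sites), `cap`
(viable through the 150 m ceiling) or `infeasible` (no viable height at
all; arid sites genuinely support no trees in-model, which is data, not an
error).  The default `metabolic_only` solver mode checks only
`Qevap ≥ Q0`; mode `both` enforces the full chain.

## Canopy energy budget

The energy budget balances total absorbed radiation against thermal
emission, sensible heat and latent heat, each acting over an effective area
proportional to the one-sided total leaf area A:

```
R_abs = c_L·A·ε·σ·T_L⁴  +  c_H·A·c_p·g_Ha·(T_L − T_air)
       + c_E·A·λ·g_v·(e_s(T_L) − e_a)/p_air
```

with defaults c_L = c_H = 2 (two-sided thermal and convective exchange) and
c_E = 1 (hypostomatous leaves).  Absorbed radiation is
`S·α·(1 − e^(−k·LAI))·A_proj` (Beer–Lambert interception of shortwave over
the projected crown area; for dense canopies this saturates at `α·S·A_proj`)
plus ambient longwave at air temperature absorbed over the thermal area with
the emissivity as absorptivity — that choice makes the no-sun,
saturated-air state an exact fixed point (T_L = T_air, E = 0), which the
tests assert to 1e-6 K.

Conductances follow the standard leaf-microclimate forms: Tetens saturation
curve `e_s(T) = 0.6108·exp(17.27·T/(T + 237.3))` kPa; boundary-layer
conductances `1.4·0.147·√(u/d)` (vapor) and `1.4·0.135·√(u/d)` (heat) for
wind speed u and characteristic leaf dimension d; stomatal conductance
linear in stomatal density through a reference pair; vapor path = stomatal
and boundary-layer conductances in series.  Molar heat capacity of air is
29.3 J mol⁻¹ K⁻¹ and the vaporization enthalpy λ = 44.0 kJ mol⁻¹ is treated
as constant.

The left side of the balance is independent of canopy temperature and the
right side strictly increasing in it, so the root is unique.  It is found by
Newton iteration with the analytic derivative, falling back to bisection on
the asserted bracket [T_air − 40, T_air + 40] °C whenever a Newton step
leaves the bracket; convergence at 1e-6 K step or residual below
1e-10·max(1 W, R_abs), 100 iterations maximum (non-convergence raises an
error carrying the last residual).  The solver is vectorized over height
grids, which is what keeps the 400-point limitation diagram and the trait
optimizations cheap.  The evaporative molar flux E at the root converts to
flow as `Qevap = c_E·A·E·M_w/ρ_w` (L/day); condensation conditions (E < 0)
are clipped to zero flow.

**Canopy albedo.**  The same Beer–Lambert closure gives the whole-canopy
albedo as `ρ_deep + (ρ_soil − ρ_deep)·e^(−k·LAI(h))`: bare-soil reflectance
for seedlings, the deep-canopy value for tall closed crowns, monotone in
between.  The sign of the trend follows from ρ_soil > ρ_deep in the default
calibration; neither ordering is enforced structurally.

## Calibration defaults and why

The shipped configuration (`allomax/data/default_config.toml`) is a
calibration of the generic tree, chosen once so that the model's regime
structure and magnitudes are ecophysiologically sensible; every value is
meant to be refit per application (`fit_scaling_law` does log–log OLS).

- `h = 2.34·D^(2/3)` (m, cm): a 100 cm trunk carries a ~51 m tree.
- `Q0`: sapling law `0.00552·D^1.9` below 5 cm, large-tree law
  `0.004·D^2.1` above, continuity-matched at the crossover (the junction is
  a hard switch; configurations whose two laws disagree by more than 5%
  there trigger a validation warning).  With leaf count ~ D^1.6 the
  required flow *per unit leaf area* grows as D^0.5, encoding the rising
  hydraulic cost of height; this is what guarantees that the evaporative
  supply per leaf eventually falls short and a metabolic crossing exists.
  A 30 m tree needs ~20 L/day of basal flow.
- Crown: radius 0.33·h, depth 0.30·h; leaf count 404·D^1.6 with 50 cm²
  single-leaf area.  This puts LAI near 3 at 30 m and lets it saturate
  around 6 for the tallest trees rather than growing without bound — deep
  hypothetical canopies with vanishing per-leaf light would otherwise
  invert the leaf-size optimum (see below).
- Roots: radial extent `1.0·h^0.8` m — seedlings start with a workable
  ~0.5 m footprint; supply grows as h^1.6, slower than evaporative demand
  (~h^2.4), so a water crossing always exists.  Root absorption efficiency
  0.25: the effective fraction of footprint rainfall a tree can actually
  use after interception and runoff losses.
- Traits: stomatal density 200 mm⁻², reference conductance 0.02 mol m⁻² s⁻¹
  at that density — an *annual-mean effective* stomatal conductance (night,
  winter and stress closure included), an order of magnitude below midday
  maxima, consistent with forcing the model with annual-mean meteorology.
  Shortwave absorptivity 0.5, extinction coefficient 0.5, emissivity 0.97,
  soil reflectance 0.30, deep-canopy reflectance 0.15, leaf dimension 5 cm.

Because evaporation is stomatally throttled, only a small share (~5–10%) of
extra absorbed radiation leaves as latent heat; most exits as sensible
exchange.  Qevap therefore has a psychrometric floor proportional to
g_v·VPD, and the limitation dichotomy follows: humid, dim sites (low VPD)
are the ones where Qevap can dip to Q0 (metabolic bound, e.g. ~60 m for a
3 m/yr, 6 °C, RH 0.93 site), while bright dry sites hit the water ceiling
within metres.

## Trait optimization

`optimal_stomatal_density` and `optimal_leaf_size` maximize the height
bound over one trait, everything else fixed, under the full constraint
chain (mode `both`) — the optimum balances enough evaporative pull to meet
metabolic demand against staying inside the water budget.  A 64-point
coarse scan locates the bracketing maximum; golden-section search refines
only inside that bracket (global unimodality is not assumed), to 0.1 mm⁻²
or 0.1 mm resolution; ties break toward the lower trait value, and the
refined point is required to dominate the coarse scan.  The objective uses
a 1 mm height tolerance so the search surface is smooth at the trait
resolution.

Along a wet/cool → hot/dry transect both optima decline with temperature.
Mechanistically: hotter, drier sites are water-bound, so lower stomatal
density (less conductance) and smaller leaves (tighter convective coupling
keeps the canopy at air temperature instead of radiatively warm, lowering
the vapor gradient) both stretch the water budget; cool humid sites are
metabolically bound and favor the opposite.  The leaf-size direction is
calibration-dependent: it requires stomata (not the leaf boundary layer) to
be the main vapor bottleneck, and per-leaf radiation loads that do not
vanish in deep canopies — the conductance and LAI defaults above provide
both, and the transect tests would catch a calibration that breaks this.

## Sensitivity analyses

- **Uniform temperature shift**: every site's air temperature is moved by
  ΔT with all traits fixed and heights recomputed; per-site percent change
  and the mean over sites feasible both before and after are reported.
  Mode `both` is the default here: without the water ceiling a uniform
  warming can only raise the evaporative bound (VPD grows with T at fixed
  RH), whereas water-bound sites lose height under warming (~ −14%/+2 °C
  per site in the default calibration) — so the aggregate sign reflects the
  regime mix.  Sites saturated at the search ceiling contribute 0%.
- **Exponent perturbation**: one scaling exponent is scaled by 1 ± p% and
  the median relative height change across a site set (or, when observed
  tallest-tree heights are supplied, the median signed relative error
  `(h_pred − h_obs)/h_obs`) is tabulated per perturbation.

## Synthetic environments

`generate_environments` replaces downloaded climatologies.  Transect mode
interpolates all variables jointly from wettest/coolest/most-humid/dimmest
to driest/hottest/least-humid/brightest (defaults: precipitation 3.0→0.3
m/yr, temperature 4→28 °C, RH 0.92→0.25, wind 1.5→4 m/s, solar 110→320
W/m² annual means, pressure 101.325 kPa), so both limitation regimes occur
in every generated set; independent mode draws uniformly within the ranges
from a seeded generator.  What the generator does **not** emulate: spatial
correlation structure between stations, elevation effects, seasonality and
diurnal cycles, and measurement error — passing tests demonstrate internal
consistency of the model on climatologically plausible annual means, not
agreement with observed tree records, which require paired tree/station
data (pairs should be within ~100 m elevation and ~4 km distance).

## Numerical choices and limitations

Problem sizes used by the test suite and the acceptance script — 1000
random environments for closure, 50 for the millikelvin grid-scan oracle,
20 closed-form draws, an 8-site transect for trends — keep a full run in
the seconds-to-minutes range while leaving each property overdetermined.

Known limitations: a single generalized tree (no species, no competition —
heights at very wet sites are over-predicted by design); annual-mean
forcing only; no CO₂ dependence of stomata; no height-dependent trait
scaling; power laws assumed over the full size range although small-tree
curvature is documented in the field; the Beer–Lambert LAI closure for
absorbed radiation and albedo is a stand-in for a full canopy
radiative-transfer treatment.
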