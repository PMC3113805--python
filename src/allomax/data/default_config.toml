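# Default calibration for the idealized average tree.
#
# These are calibration values chosen to give a physically sensible generic
# tree (heights of metres to ~100 m across temperate climates, LAI of a few,
# basal flows of tens to hundreds of litres per day for mature trees). They
# are meant to be refit per application with `fit_scaling_law`; see
# docs/methods.md for the reasoning behind each default.
#
# Units contract: heights/radii in m, trunk diameters in cm, flows in L/day.

schema_version = 1

[allometry]
crossover_diameter_cm = 5.0
leaf_area_single_m2 = 0.005

# Tree height (m) from trunk diameter (cm); elastic-similarity exponent 2/3.
[allometry.height_vs_diameter]
prefactor = 2.34
exponent = 0.6666666666666666
input_units = "cm"
output_units = "m"

# Basal metabolic flow (L/day) from trunk diameter (cm), sapling regime.
# Prefactor continuity-matched to the large-tree law at the crossover:
# 0.004 * 5^0.2.
[allometry.basal_flow_small]
prefactor = 0.00551892
exponent = 1.9
input_units = "cm"
output_units = "L/day"

# Basal metabolic flow (L/day) from trunk diameter (cm), large-tree regime.
# Slightly super-quadratic: with leaf count ~ D^2 the required flow per leaf
# grows as D^0.1, encoding the rising hydraulic cost of height, so the
# evaporative supply per leaf eventually fails to cover it.
[allometry.basal_flow_large]
prefactor = 0.004
exponent = 2.1
input_units = "cm"
output_units = "L/day"

# Canopy radius (m) from tree height (m).
[allometry.canopy_radius]
prefactor = 0.33
exponent = 1.0
input_units = "m"
output_units = "m"

# Canopy depth (m) from tree height (m).
[allometry.canopy_depth]
prefactor = 0.30
exponent = 1.0
input_units = "m"
output_units = "m"

# Radial extent of the root system (m) from tree height (m); sublinear, so
# seedlings start with a workable footprint and supply grows as h^1.6.
[allometry.root_radius]
prefactor = 1.0
exponent = 0.8
input_units = "m"
output_units = "m"

# Number of leaves from trunk diameter (cm); sub-quadratic so the leaf area
# index saturates near 6 for the tallest trees instead of growing unbounded.
[allometry.leaf_count]
prefactor = 404.0
exponent = 1.6
input_units = "cm"
output_units = "count"

[water]
root_absorption_efficiency = 0.25

[traits]
stomatal_density_per_mm2 = 200.0
reference_stomatal_density_per_mm2 = 200.0
reference_stomatal_conductance_mol_m2_s = 0.02
leaf_characteristic_dimension_m = 0.05
leaf_shortwave_absorptivity = 0.5
canopy_extinction_coefficient = 0.5
thermal_emissivity = 0.97
soil_reflectance = 0.30
deep_canopy_reflectance = 0.15
effective_area_thermal = 2.0
effective_area_sensible = 2.0
effective_area_evaporative = 1.0
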