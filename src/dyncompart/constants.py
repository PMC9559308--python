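"""Physical constants and package-wide defaults.

All unit conversions between the trace-processing side (SI: Pa, m, s) and
the kinetics side (kg/m^3, hr) are funnelled through the values defined
here so that no module carries its own copy of a conversion factor.
"""

#: Gravitational acceleration [m/s^2].
G = 9.81

#: Reference pressure for gas volumetric flow rates ("normal" m^3) [Pa].
P_REF = 101_325.0

#: Reference temperature for gas volumetric flow rates [K].
T_REF = 298.15

#: One standard atmosphere [Pa], used in Henry's-law conversions.
ATM = 101_325.0

#: Default broth (liquid) density [kg/m^3].
RHO_L_DEFAULT = 1030.0

#: Density of air at process conditions [kg/m^3]; only enters the
#: dispersion density as a sub-0.1% correction.
RHO_G_DEFAULT = 1.2

#: Mole fraction of oxygen in air.
X_O2 = 0.2095

#: Henry solubility of oxygen in water at 306 K [mol/L/atm].
HENRY_CP = 0.0015

#: Molar mass of O2 [kg/mol].
M_O2 = 0.032

#: Coefficient of the linear kLa correlation, kLa = KLA_COEFF * v_s,
#: with kLa in 1/hr and v_s in m/s (taken at face value from the source
#: correlation; see docs/methods.md for the unit discussion).
KLA_COEFF = 0.288

#: Seconds per hour.
S_PER_HR = 3600.0

#: Critical local residence time for auto-zoning [s].
TAU_CRIT_DEFAULT = 1.5

#: Initial compartment slab height [m].
DZ0_DEFAULT = 0.5

#: Compartment-model update interval [s].
DT_UPDATE_DEFAULT = 3600.0

#: Minimum velocity-sample count required at any retained interface.
MIN_SAMPLES_DEFAULT = 30
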