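# Methods

`dyncompart` builds a *dynamic compartment model* of a bubble-column
fermenter from flow-following sensor data and uses it to simulate tracer
mixing and fed-batch fermentation gradients.  This note records the
models, the numerical choices, and the limits of what the synthetic test
bed can demonstrate.

## 1. From pressure traces to axial kinematics

A flow-following sensor device is a near-neutrally-buoyant sphere that
rides the broth circulation and logs absolute pressure `P(t)` and
temperature at 1 Hz.  Its height above the vessel bottom follows from
hydrostatics (Pascal's law):

    z(t) = (P_max(t) − P(t)) / (ρ_f · g)

`P_max(t)` is the dynamic bottom-pressure envelope.  It absorbs three
confounders — headspace-pressure drift, liquid-volume growth from feeding,
and density changes — and is estimated by a centred rolling **maximum**
over 1 hr (the device is assumed to visit the bottom at least hourly)
followed by a centred rolling **average** over 600 s.  The smoothing
window is not fixed by any physical constraint; 600 s removes the
staircase artifacts of the maximum filter while staying well below the
1-hr envelope time scale.  Both windows are configurable.

The dispersion density `ρ_f = (1−ε)ρ_l + ε·ρ_g` uses the gas hold-up from
the heterogeneous-churn-flow correlation

    ε = v_s / (0.25 + 0.45 (g v_s D)^{1/3})

with the superficial gas velocity `v_s` obtained from the sparger flow
(normal m³/s) by ideal-gas rescaling to process pressure and temperature.

**Pressure reference for the hold-up correction.**  Pascal's-law
inversion uses a *single* instantaneous density, i.e. it models the
dispersion as height-uniform at each instant.  Evaluating `v_s` at the
pressure measured at the device's own depth would contradict that
assumption (the implied density would depend on where the device happens
to be, producing a few-percent position bias at the column ends), so the
default corrects `v_s` to the instantaneous *column-mid* pressure — the
mean of the rolling bottom (max) and top (min) pressure envelopes.
Device-local correction is available via `pressure_correction="device"`.

Axial velocity is the central finite difference of `z(t)` after an
optional 5-s moving average (enough to suppress 1 Hz pressure noise of
O(100 Pa), which maps to only ~2 cm of position noise; the derivative
details of the original instrument papers are not public, so this is the
package's own choice).  Positions are clipped to `[0, H_L(t)]`, with the
instantaneous gassed liquid height taken from the envelope span
`(P_max − P_min)/(ρ_f g)`.

When several devices with different densities are deployed, the model is
built from the devices whose density is closest to the time-averaged
dispersion density (they track the liquid best); pooling all devices is a
configuration option.

## 2. Dynamic compartment model

The liquid is cut into axial slabs of height `dz0 = 0.5 m`.  Time is cut
into update steps of `dt_update = 1 hr`; within a step, volumes and flows
are frozen.  Per step *j*:

- `H_L` from the pooled pressure span of all selected devices;
- slab volumes `V_k = A·Δz_k·(1−ε_k)` — both volumes and flows are scaled
  by the liquid fraction, because gas occupies part of every interface
  and slab;
- interface exchange flows `Q_k = A·(1−ε_k)·⟨|v_z|⟩_k / 2`, where
  `⟨|v_z|⟩_k` is the mean speed of all samples within half a slab height
  of the interface.  The symmetric half/half split of up- and down-flow
  enforces the zero-net-flow closure of a batch column.  At least
  `min_samples = 30` velocity samples are required at every interface;
  a step that violates this is re-discretised at doubled slab height (up
  to three times) before the builder raises an error.
- per-slab mean pressure, temperature and hold-up (used later for kLa and
  oxygen saturation); empty slabs are filled by linear interpolation
  across slab centres.

**Auto-zoning.**  Slabs are merged bottom-up into ideally mixed zones
while the candidate zone's local residence time `τ = ΣV / min(internal Q)`
stays below the critical residence time `τ_crit = 1.5 s`.  Merging is
greedy first-fit from the bottom (the original ordering is not published;
first-fit is deterministic and monotone: scaling all flows up never
increases the zone count).  The flow retained at a zone boundary is that
interface's own flow — internal interfaces cease to exist.

The vessel bottom is treated as cylindrical; the real dished head would
reduce the bottom-zone volume slightly.

## 3. Tracer mixing

On a zoned step the pulse-tracer problem is linear:

    dC_k/dt = [Q_{k−1}(C_{k−1} − C_k) + Q_k(C_{k+1} − C_k)] / V_k

integrated with LSODA (rtol 1e-10).  Homogeneity is scored by the
volume-weighted RMS of the log10 normalised responses,

    m(t) = sqrt( Σ_k w_k (log10 C_k/C_inf)² ),   w_k = V_k / ΣV,

with `C_inf` the volume-weighted mean concentration 10 min after the
pulse.  `t_m95` is the last crossing of `m` below `|log10 0.95| ≈ 0.0223`
(bracketed on the output grid, refined by root-finding on the continuous
solution), so in the single-worst-zone limit the criterion coincides with
the conventional "every zone within ±5%".  The exact formula behind the
published "logarithmic root-mean-square variance" wording is not given
anywhere; an unweighted variant is provided for comparison.  Responses
are floored at 1e-6 before the log so the metric stays finite ahead of
the tracer front.  If the metric has not settled within the horizon the
horizon doubles adaptively up to 1e5 s; a network with a zero-flow
interface reports `inf`, never a silent number.

Because the system is linear, `t_m95(αQ) = t_m95(Q)/α` exactly; the test
suite asserts this to 0.5% and checks 2- and 3-zone transients against
matrix-exponential closed forms.

## 4. Fed-batch fermentation

Per zone, four states (kg/m³): biomass `C_x`, substrate `C_s`, product
`C_p`, dissolved oxygen `C_o`.  Kinetics (time in hours):

    µ   = µ_max · C_s/(C_s+K_s) · C_o/(C_o+K_o) · (1 − C_p/K_p)
    r_p = Y_px·µ + r_xp                (growth + non-growth production)
    r_s = µ/Y_xs + r_p/Y_ps + r_ms     (uptake incl. maintenance)
    r_o = r_s/Y_so + r_mo

µ may be negative above the critical product concentration `K_p` (cell
death).  Feed enters the top zone only, constant within a step, and does
not change the step's volume (volume growth is carried by the next
step's geometry).  Oxygen transfers at `kLa·(C* − C_o)` with Henry's-law
saturation at the zone's mean pressure (`H_cp = 0.0015 mol/L/atm` at
306 K, pure-water assumption; mole fraction of O₂ in air 0.2095, no
gas-side depletion along the height).

**Starvation gating.**  The literal equations keep maintenance and
non-growth production running at `C_s = 0`, which would drive
concentrations negative.  Maintenance and non-growth terms are therefore
multiplied by a smooth gate `C_s/(C_s + 10⁻³ kg/m³)`, and oxygen uptake
by `C_o/(C_o + 10⁻⁵ kg/m³)` — negligible distortion at healthy
concentrations, zero uptake at exhaustion.

**kLa units.**  The linear correlation is used with its printed constant,
`local_kla(v_s) = 0.288·v_s` with kLa in 1/hr and v_s in m/s, and the
constant is exposed in the configuration.  Taken at that face value, a
production bubble column at `v_s ≈ 0.2 m/s` would get kLa ≈ 0.06 1/hr —
three orders of magnitude below any aerobic fermenter, and the broth
would be anoxic in minutes.  The reference synthetic scenario therefore
reads the correlation with `v_s` in m/hr (equivalently, coefficient
0.288·3600 ≈ 1037 per (m/s)·hr), which lands kLa in the normal
100–400 1/hr range of industrial aerated fermenters.

**Inter-step re-binning.**  Final concentrations of step *j* become
initial conditions of step *j+1* by a conservative three-stage map:
concentrations → masses (×`V_j`); masses diluted into temporary
compartments (step-*j* geometry scaled by `V_{j+1}/V_j`); masses
redistributed to step-*j+1* compartments by fractional volume overlap
(a compartment split in half passes half its mass to each part).  The
implementation exploits that cumulative mass is piecewise linear in the
cumulative-volume coordinate, so the map is exact to machine precision
(tested to 1e-12 over random geometry pairs).

**Solver.**  LSODA (stiff/non-stiff switching), rtol 1e-8, atol 1e-10 by
default, both configurable.  An extra quadrature state integrates total
substrate consumption so the balance `fed − Δinventory = consumed`
closes to solver precision.  Rates are evaluated on concentrations
floored at zero; DO stays within `[0, max_k C*_k]` up to integrator
tolerance.

## 5. Calibration

The objective is the sum of squared errors between simulation and
observations: biomass/substrate/product compare against the
volume-weighted height-average concentration, DO against the zone
containing the probe height (5.85 m).  Because the variables span four
orders of magnitude (product ~100 kg/m³ vs DO ~0.01 kg/m³), the default
weights are 1/variance of the observed values per variable; plain
unweighted SSE is available.  Minimisation is Nelder–Mead on
log-transformed parameters (positivity without constraints; a raw
unconstrained mode exists).  A failed simulation returns a large finite
penalty so the simplex can retreat.  Default budget 2000 evaluations;
the recovery studies use 300 with `xatol = 10⁻³` (0.1% in log space) and
`fatol = 10⁻⁴`, which converge in ~100–150 evaluations.

Identifiability is verified by recovery: simulate with known truth, add
5% multiplicative lognormal noise at 15 sampling times, fit from a
deliberately wrong start (+40% µ_max, −30% K_p, +30% Y_px), repeat over
ten observation seeds.  µ_max, K_p and Y_px recover with median errors
well under 10%.  Parameters the design cannot see — K_o when DO is never
limiting, K_s when substrate is always far above it — are reported by
`recovery_report` as practically unidentifiable rather than forced.

## 6. The synthetic plant

The virtual reactor supplies every input with known truth:

- geometry `D = 5.3 m` (A ≈ 22.1 m²), gassed height ramping 16 → 26 m
  linearly over a 32-hr fed-batch;
- gas flow 4.75 Nm³/s with a rampdown to 1.4 Nm³/s after 15 hr; feed
  ramping 0.3 → 1.6 kg/s over 3 hr, stepped down to 0.9 kg/s at 24 hr;
  headspace 121.3 kPa with a slow 3 kPa drift;
- a two-loop axial circulation with peak speed `0.9·(g·v_s·D)^{1/3}`
  (the classical circulation-velocity group, ~2 m/s at full aeration)
  and weak ends (12% of peak), shaped by `sin(π·z/H_L)`;
- the device is a telegraph random walk: it moves at the local field
  speed, reverses direction with a 150-s mean persistence time, and
  reflects at the bottom and the moving surface.  Pressure is
  `P_head + ρ_f(t)·g·(H_L − z)` plus white noise (σ = 200 Pa default),
  temperature a constant 306 K.  Both the noisy trace and the exact
  `z, v_z` truth are returned.
- kinetic truth = the packaged `KineticParameters` defaults — explicitly
  *placeholder* magnitudes for an aerobic glucose-to-diol E. coli
  process (µ_max 0.4 1/hr, K_p 110 kg/m³, Y_ps 0.5, ...), chosen so the
  scenario reproduces the qualitative fed-batch signature: productivity
  rising to ~5.6 kg/m³/hr then declining under product inhibition, a
  substrate-depleted mid-process window, DO dipping during peak demand,
  final titre ~90 kg/m³.  They are not fitted plant values.

Two model-construction routes exist deliberately: the *data route*
(particle walks → trace processing → builder) exercises the estimation
chain and is validated against truth; the *analytic route*
(`synthetic_compartment_model`) evaluates volumes and flows directly
from the prescribed field and is the fast deterministic backbone for
mixing/fermentation/calibration studies (32 steps build in ~0.1 s).

**What the synthetic plant does not emulate:** radial motion and
radially non-uniform hold-up, bubble-scale pressure fluctuations,
device–device interactions, density stratification, broth rheology
changes, sensor drift, and biological adaptation or stress memory.
Passing the round-trip and recovery tests therefore demonstrates the
*estimation machinery* is correct under the stated assumptions, not that
those assumptions hold in any particular plant.

## 7. Problem sizes and degenerate inputs

- Reference studies run J = 32 hourly steps at 0.5-m slabs (25–52 zones
  after merging).  Calibration/recovery studies use a coarsened model
  (6-m slabs, 4-hr updates, 3–4 zones) — kinetic-parameter information
  lives in the height-averaged trajectories, which the coarse model
  reproduces, and ten Nelder–Mead fits then take minutes.
- The liquid-height estimator's resolution is limited by sampling
  granularity near the reflecting boundaries (speed × 1 s); a
  constant-speed field whose height is an exact multiple of that step is
  a degenerate resonant case and is avoided in tests.
- Single-zone steps short-circuit the tracer solver (`t_m95 = 0`);
  zero-flow interfaces are never merged by zoning and make the mixing
  time report `inf`.
- A trace shorter than the rolling window, a non-monotone time axis,
  non-positive pressures/densities, or an observation table with unknown
  variables all raise immediately with the offending field named.
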