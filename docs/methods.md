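# Methods

This note documents the model as implemented: its assumptions, the
parameters that matter, what the synthetic weather generator does and does
not emulate, the numerical choices, and known limitations.

## Scope and time stepping

The simulator advances an olive orchard one day at a time, starting on
January 1 (phenology state is pre-run on at least 90 days of prior daily
mean temperatures). Processes with strong diurnal structure — root water
uptake, leaf gas exchange, maintenance respiration, chilling — run on N
equal sub-daily steps (default N = 24). Within a day the order of
operations is fixed: weather disaggregation → phenology → management events
→ canopy interception and wet-canopy evaporation → per-zone runoff,
infiltration, drainage, redistribution → the diurnal SPAC loop → soil
evaporation → the carbon economy → geometry and root-length updates → soil
carbon → closure audits. This ordering is a design choice of this
implementation; within-day coupling between the morning infiltration and
the day's uptake is therefore explicit (uptake sees the post-infiltration
profile, frozen for the day).

## Weather disaggregation and synthesis

Daily forcing (Tmax, Tmin, ea, global radiation, wind, rain) is split into
N steps. Temperature follows a sine from Tmin at sunrise to Tmax at 14:00,
then an exponential night decay toward Tmin (N = 1 degenerates to the daily
mean). Radiation is distributed proportionally to max(sin β, 0) of solar
elevation and renormalised, so ∑(step flux × Δt) equals the daily total
exactly. PAR is 0.45 of global; the beam/diffuse split uses a daily
clearness-index correlation (overridable). Vapor pressure and wind are held
constant over the day — only daily means are input, and inventing diurnal
humidity structure would add parameters without data to constrain them.

The synthetic generator emulates a semi-arid Mediterranean climate:
sinusoidal annual cycles of temperature (18 ± 9 °C) and diurnal range with
AR(1) day-to-day noise, radiation as a clear-sky fraction of
extraterrestrial (reduced on rain days), and rainfall from a seasonal
occurrence probability (wettest mid-winter, mean daily probability 0.18)
with gamma-distributed amounts averaging 9 mm — about 600 mm yr⁻¹,
concentrated outside summer. It does not emulate multi-day synoptic
persistence beyond the temperature AR(1), heat-wave/drought compound
structure, or inter-annual climate modes; a green test on this weather
establishes internal consistency and plausible behaviour, not predictive
skill at a real site.

## Soil water

Each zone (wetted fraction f, dry fraction 1 − f; a single zone when
f = 0) has layers with field capacity θ_UL = 0.23, wilting point
θ_LL = 0.07, saturation 0.40 (sandy loam defaults; all per-layer
configurable). Effective rain is the same depth on both zones; irrigation
(orchard-basis mm ÷ f) enters the wetted zone only, below the canopy, so
it bypasses interception and runoff. Runoff uses the SCS curve number with
a three-class antecedent-moisture adjustment from topsoil plant-available
water; tillage events shift CN. Drainage is a tipping bucket (rate SWCON =
0.4 d⁻¹ of the excess above θ_UL, capped at saturation of the receiving
layer), followed by a diffusive relaxation of relative-wetness differences
between adjacent sub-field-capacity layers. Soil evaporation is two-stage:
stage 1 at the Penman potential × transmitted-radiation fraction ×
microadvection factor (1.3 for the small wetted patch, 1 for the dry zone);
after U_stage1 = 9 mm cumulative, stage 2 follows α(√t − √(t−1)) with α =
3.5 mm d^-1/2. Extraction comes from the top two layers down to an air-dry
floor (0.5 × θ_LL). Partial rewetting offsets the stage-1 total
(Ritchie-style) rather than always resetting it.

## Crown geometry and radiation

Crowns are spheroids with constant leaf area density and fixed
vertical:horizontal radius ratio R_zx on a regular planting grid. Leaf
area = biomass × SLA; volume = area / LAD; radii follow from the volume and
are capped by spacing and maximum height, re-densifying LAD so leaf area is
never lost. Beam transmission of one crown uses the exact chord-length
distribution of an ellipsoid (the sphere formula T = 2(1 − (1 + τ)e^(−τ))/τ²
with τ the optical depth of the longest chord; an ellipsoid is an affine
image of a sphere, and along a fixed direction all chords scale by one
factor, so the sphere result carries over exactly). Neighbor shading treats
the expected number of crowns crossed by a ray, μ = A_proj/(sin β · cell
area), as a regular tiling: ⌊μ⌋ certain crossings plus one more with
probability frac(μ). This is exact for non-overlapping shadows and a mild
approximation otherwise; a Monte-Carlo ray-casting oracle in the test suite
bounds the error at 5 % for representative geometries. Diffuse radiation
integrates the beam model over five elevation bands of a uniform sky.
Sunlit leaf area is f_beam·sin β / G (G = 0.5, spherical leaf angles);
scattering reaches shaded leaves through a single correction factor (0.10)
rather than a multi-stream treatment.

## SPAC and gas exchange

Soil-to-collar branches combine a Gardner/Cowan rhizosphere resistance
(log-spacing geometry over unsaturated conductivity k_sat(θ/θ_sat)^(2b+3))
and a root radial resistance (1 / (permeability × root surface area), with
permeability reduced in dry soil and below 20 °C). Campbell retention
(Ψ_e = −0.003 MPa, b = 3.6, giving ≈ −1.5 MPa at θ_LL) maps water content
to potential; a gravity head of 0.01 MPa m⁻¹ offsets each layer and the
canopy. The xylem resistance comes from sapwood-specific conductivity
(5.5 × 10⁴ mmol m⁻¹ s⁻¹ MPa⁻¹), sapwood area per ground (6 × 10⁻⁴) and
path length (height + crown radius); defaults put whole-plant resistance
near 0.35 MPa s m² mmol⁻¹, a realistic olive value. Reverse flow (hydraulic
redistribution) is allowed by default (`allow_efflux`); clamping prunes
losing branches iteratively.

Leaf biochemistry is a standard C3 model (Rubisco- and RuBP-limited rates,
Bernacchi temperature responses, J from a non-rectangular hyperbola with
Jmax = 1.8 Vcmax; Vcmax25 = 70 µmol m⁻² s⁻¹). A′ is gross (dark respiration
lives in the whole-plant maintenance budget, not subtracted per leaf).
Stomata follow a Leuning form g_s = g0 + g1·A′/((Ca − Γ*)(1 + VPD/D0)) ×
f(Ψ_l), with f a logistic falling from 1 near −1 MPa to ~0 at −5 MPa
(olive stomata stay open to unusually low potentials). Leaf temperature
equals air temperature — the canopy is treated as aerodynamically
well-coupled, which is also why transpiration uses the imposed-evaporation
form rather than full leaf energy balance.

Numerics: the Ci loop and the outer Ψ_l loop are damped fixed-point
iterations (damping 0.5, tolerances 0.1 µmol mol⁻¹ and 0.005 MPa, 50
iterations); both maps can two-cycle under strong stomatal feedback, so
each falls back to bisection on its residual — the Ci residual brackets a
root on [0, Ca] and the Ψ_l map is monotone decreasing, so both fallbacks
are unconditionally convergent. Non-convergence raises; it is never
silently absorbed. A supply cap E_p,crit = (Ψ̄ − gravity − Ψ_min)/R_total
(Ψ_min = −8 MPa) prevents the cuticular conductance floor (g0) from
driving the leaf potential to unphysical values in very dry soil; hitting
the cap flags the step as supply-limited.

## Phenology

Chilling accumulates sub-daily with a triangular effectiveness (0 at 0 °C,
1 at 7 °C, 0 at 14 °C) toward a requirement of 40 chill-day equivalents;
release ends dormancy. Flowering needs 400 °Cd of post-release forcing
above 10 °C (two-phase scheme). Vegetative growth resumes when the 7-day
trailing mean temperature exceeds 12 °C; fruit growth runs from 250 °Cd
after flowering to maturity (2200 °Cd) or harvest. The dormancy cycle
resets on November 1. The chilling function is an explicit stand-in — the
literature model it replaces has unpublished constants here — and is
designed to be swapped via the parameter block.

## Carbon economy

Substrate accounting is in g CH₂O m⁻², biomass in g DM m⁻². The day's pool
is A′ (+ fruit photosynthesis, a linear coefficient on fruit biomass while
fruits grow) minus maintenance respiration (per-organ coefficients at
20 °C, Q10 = 2, summed sub-daily); deficits draw reserves first
(starvation floors the pool at zero and reduces the respiration actually
paid — unmet maintenance is not tracked as damage). When fruit demand
(FN × 4 × 10⁻⁴ g DM fruit⁻¹ °Cd⁻¹, converted through PV_fruit) exceeds the
pool, up to 5 % of reserves per day is remobilized. Fruits take
min(demand, pool); the rest splits by fixed vegetative coefficients
(leaves 0.20, shoots 0.15, branches 0.25, coarse roots 0.15, fine roots
0.25); out-of-season substrate accrues to reserves. Production values
(0.68–0.70 vegetative, 0.55 for the oil-rich fruit) convert substrate to
structure.

Carbon audits convert CH₂O at 12/30 g C g⁻¹ and biomass at 0.45 g C g⁻¹ DM.
These constants are mutually inconsistent if growth respiration is defined
as (1 − PV) × substrate in CH₂O units, so growth respiration in carbon
units is defined as the residual, substrate C − biomass C =
s·(0.40 − 0.45 PV) — positive for all PV < 0.89 — which makes the
whole-system carbon balance close to machine precision by construction.
The closure tests therefore verify bookkeeping integrity (no flux lost or
double-counted), not the constants themselves.

Fruit number for a season is set at fruit-growth onset:
FN = max(0, 1.5 × nodes_prev − 0.7 × FN_prev), reduced 10 % per day with
Tmax > 37 °C in the 10 days after flowering. Nodes are 3 per g of shoot
growth. The negative feedback coefficient (0.7) produces the strong ON/OFF
alternation characteristic of olive; with the default weather it yields a
lag-1 autocorrelation of annual fruit yield near −0.9 and biennial means
far steadier than annual ones. The first season seeds FN from the prior
year's dry yield ÷ mean fruit mass (0.6 g) and a steady-state node count.

Leaves turn over at 1/900 d⁻¹ (~2.5-year lifespan), fine roots at
0.003 d⁻¹; litter and incorporated pruning residues feed a two-pool soil
carbon model (fresh 0.02 d⁻¹, humus 8 × 10⁻⁵ d⁻¹, humification 0.2, Q10 and
a moisture modifier peaking near field capacity). Shoot cohorts age each
January 1; the 3-year cohort becomes branches.

## Management

Irrigation: explicit dated events, or the auto rule — every 7 days in the
April–October window, apply fraction f (default 1.0) of the maximum ET
accumulated since the last application, net of effective rain. Maximum ET
is the model's own Penman potential scaled by a ground-cover coefficient
min(1, 0.30 + 1.2·GC): a deliberate simplification of "unstressed ET"
that avoids running a second, well-watered copy of the whole model each
day while still tracking canopy size. Harvest (day 349) removes fruits and
archives FN; oil yield is 0.42 × fruit DM. Pruning (every 2 years, day 60)
removes fraction F_prune of leaves, shoots and branches, with residues
incorporated or exported. Tillage edits CN.

## Audits and tolerances

Water and carbon are audited daily: the cumulative in − out − Δstorage
residual must move by less than 10⁻⁶ (mm, g C) per day or the simulation
aborts with the flux breakdown. Zone-level fluxes carry their own closure
invariant (10⁻⁶ mm), drainage conserves to 10⁻⁹ mm, allocation substrate
to 10⁻⁹, the network's Kirchhoff sum to 10⁻⁹. In decade-long runs the
per-year residuals sit near 10⁻¹¹ — any genuine bookkeeping error trips
the audit immediately.

## Known limitations

- No within-tree water storage: simulated diurnal transpiration leads
  sap-flow-style observations; stomata respond instantaneously.
- Oil accumulation dynamics inside the fruit are not modelled (fixed
  oil:DM ratio at harvest), nor are nutrients, pests or diseases.
- One representative tree per orchard; no row/hedgerow geometry, no
  azimuthal anisotropy in the neighbor-shading term.
- The chilling model, CN adjustment table, senescence and soil-carbon pool
  constants are documented stand-ins with exposed parameters, not fitted
  reproductions of any published calibration.
- Soil temperature is approximated by air temperature in root permeability
  and decomposition.
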