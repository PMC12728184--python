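# Model description and methods

`treedsim` simulates how terrestrial vegetation responds, through trait
evolution and dispersal, to an abrupt deep-time warming event, and what
that response does to terrestrial carbon storage and silicate weathering.
A single *reference plant* per land cell carries six key traits — height
H, leaf carbon pool C_leaf, leaf longevity a_ll, phenology (deciduous or
evergreen), fine-root:leaf ratio r:s, and a climatic niche (coldest-month,
warmest-month and mean annual temperature of the environment it is adapted
to).  Every 10 kyr step the model asks which trait combination the local
climate *selects for*, lets the resident vegetation evolve a stochastic
fraction of the way there, disperses offspring, and resolves competition.

## Annual carbon balance

For one plant in one cell, with monthly climatologies of temperature,
precipitation and downwelling shortwave radiation:

* **Leaf economics.** SLA = 2·10⁻⁴ · (1/DM_c) · 10^(2.25 − 0.5·log₁₀(12·a_ll))
  with DM_c = 0.47 g C per g dry matter: short-lived leaves are cheap per
  area, long-lived leaves dense (LMA = 1/SLA).
* **Light capture.** LAI = C_leaf·SLA/CA; APAR = 0.5·RSDS ·
  (1 − e^(−k·LAI)) · α_leaf:stand · Φ, where k is 0.6 for deciduous plants
  with a_ll < 1 yr, 0.4 for a_ll > 4 yr, 0.5 otherwise.  Φ ∈ [0,1] is the
  climatic-niche stress, the minimum of three Gaussian penalties
  exp(−k_nb·ΔT²) on the coldest-month, warmest-month and annual-mean
  deviation between local climate and the plant's niche; k_nb ∈ {0, 0.03,
  0.10} spans no / intermediate / strong niche limitation (0.03 leaves
  ~5% of productivity at a 10 °C deviation).
* **Photosynthesis.** A light-use-efficiency formulation: gross daily
  assimilation is the minimum of a light-limited rate (∝ APAR) and a
  Rubisco-capacity cap, scaled by a trapezoidal temperature-inhibition
  factor (full activity 12–38 °C, zero at 0/55 °C), a CO₂ factor
  (c_i − Γ*)/(c_i + 2Γ*) with c_i = λ·c_a, and two stature factors: a
  hydraulic limitation 1/(1+(H/150 m)²) and a stand light-capture term
  1 − 0.3·e^(−H/10 m) (short stands lose light to sub-canopy levels; this
  is what makes height carbon-profitable and aligns carbon optimality
  with light competition).
* **Closed water balance.** AET = min(E_supply, E_demand) each month;
  E_supply is precipitation, E_demand = E_eq·α_m/(1 + g_m/g_c) with the
  Priestley–Taylor equilibrium rate E_eq, α_m = 1.391, g_m = 3.26 mm s⁻¹
  and canopy conductance g_c = 1.6·A_dt/(c_a(1−λ)) + g_min.  Under ample
  water λ = λ_max = 0.8; otherwise λ solves E_demand(λ) = E_supply by
  bracketed bisection (the production code uses 60 halvings by default —
  machine precision; the engine uses 16 for throughput, documented below).
* **Respiration and NPP.** NPP = (1 − r_gr)(GPP − R_leaf − R_sapwood −
  R_fineroot) with r_gr = 0.25.  Sapwood and fine-root respiration are
  proportional to tissue nitrogen (C over C:N, per crown area) with a
  Lloyd–Taylor temperature response; leaf respiration is proportional to
  leaf *area* (leaf N per area varies little along the leaf-economics
  spectrum, so thin cheap leaves do not respire for free).
* **Turnover and net carbon gain.** Woody pools pay C·f·(1+HD+FD) per
  year (f = 0.05/0.01/0.05 yr⁻¹ for sapwood/heartwood/coarse roots; HD and
  FD are degree-month heat/frost indices jointly capped so the factor
  never exceeds 2).  Leaves cost C_leaf/a_ll per year if evergreen and the
  full pool if deciduous; fine roots mirror leaves for a_ll > 1.
  NCG = NPP − Στ/CA is the fitness measure: the surplus left for
  reproduction, defence and everything else.

### Allometry

Crown area CA = max(0.013·C_leaf^0.75·H^0.25 + 0.1·H, 1 m²).  Sapwood
follows the pipe model on a leaf-*area* basis (55 g C per m² leaf per m of
height) plus a structural term (50 g C per m² crown per m); heartwood
accumulates as 2.2 g C per m² leaf per m²-of-height; coarse roots are 25%
of the stem.  The area basis matters: with mass-based pipes, high-SLA
leaves evade the woody budget and degenerate micro-leaf strategies win the
optimisation.  These constants were calibrated once against present-day
magnitudes (tropical GPP ≈ 3000–3500 g C m⁻² yr⁻¹, LAI ≈ 5, canopy heights
10–45 m from arctic shrub to tropical forest, biomass densities 25–250
Mg C ha⁻¹) before any warming experiment was run.

## Trait optimisation

Per cell and CO₂ level, a seeded differential evolution searches
(C_leaf, a_ll) log-uniformly in [10, 10⁵] g C × [1/12, 10] yr, separately
for the evergreen case and — where more than 3 months fall below 3 °C —
the deciduous case (a_ll ≤ 1), keeping the better phenology.  Height is
not a free dimension: each candidate is evaluated at its own *maximum
potential height*, the height at which NCG/NPP declines to 0.2 (bisection
on the descending branch of the hump-shaped ratio curve; candidates whose
ratio never reaches 0.2 live at their peak-ratio height, and candidates
are viable iff NCG > 0).  The scalar API additionally re-runs the search
under a linear a_ll axis and polishes the winner with a deterministic
multi-start pattern search in log-log space, making the result invariant
to the axis parameterisation; the grid engine uses the economical
single-axis search.  The optimiser RNG derives from a fixed constant, the
CO₂ level and the phenology case — the optimum is a property of the
environment, not of the scenario — so targets are cached per CO₂ level
and shared across scenario seeds and α values.

## Eco-evolutionary stepping

Per 10 kyr step: (1) targets from the optimiser; (2) adaptation —
C_leaf and a_ll move a fraction Normal(α, 0.05) (clipped to [0,1], drawn
independently per trait and cell) of the way to the target, the niche
temperatures move likewise towards the *local* coldest/warmest/mean
temperatures, and the plant turns deciduous iff deciduousness is favoured
locally and the new a_ll ≤ 1; (3) each plant draws a Weibull(shape 1.75,
scale = dispersal parameter) distance and places trait-identical offspring
in every land cell within it (great-circle distances); (4) competition:
candidates with NCG ≤ 0 die; among the rest the winner maximises
NCG · S(H; H̄), S a logistic penalty (k_h = 0.2 m⁻¹) around the mean
candidate height.  Height is fully dynamic — every candidate is evaluated
at its maximum potential height in the *destination* cell (offspring
inherit the six key traits, not the realised stature).  The
pre-adaptation incumbent also competes in its own cell, so selection
cannot fix a trait move that lowers fitness in place; this guards the
stationary state against the finite optimality gap of the batch search,
which otherwise drives a permanent adapt-regress/migrant-repair
oscillation of a few percent in the global stocks.

Randomness uses one master seed split into per-(step, purpose) child
streams; with identical configuration and seed a run is bit-reproducible.

## Forcing

CO₂ follows a piecewise-linear timeline: 50 kyr at 680 ppm, a step to
1590 ppm across one 10 kyr step, a 70 kyr plateau, linear decline to
780 ppm at +150 kyr and to 680 ppm at +200 kyr.  Monthly climatologies are
interpolated linearly in CO₂ between two endmember states (log-CO₂
interpolation is available as an option).  The synthetic world generator
builds those endmembers on an n_lat × n_lon sphere: a zonal mean-annual
temperature profile (28 °C equator, −6 °C poles), seasonality growing with
|lat|, wet tropics + mid-latitude storm tracks + multiplicative spatial
noise, radiation from daily-mean solar geometry, a seeded low-frequency
land mask (35% land) and lognormal slopes.  The warm endmember applies a
warming field with poleward amplification (+60% at the poles), seeded
regional heterogeneity (±35%, emulating the maritime/continental contrasts
of GCM warming patterns — the low-warming regions act as refugia) and
winter-dominated seasonality (cold months warm 1.4×, warm months 0.6× the
local mean — so the seasonal cycle flattens poleward, as coupled models
robustly show), renormalised so the land-area-weighted mean equals the
requested offset exactly; precipitation scales by +2% per local °C.
What the generator does *not* emulate: realistic continental geometry,
orography, monsoons, interannual variability, or soil moisture memory —
simulation results on it demonstrate mechanisms, not geography.

## Carbon and weathering diagnostics

Treating each occupied cell as closed canopy, per-crown-area fluxes are
scaled by spherical cell areas.  Soil carbon is the steady-state stock
C_soil = NPP/(k·Q10^((T−15)/10)) with k = 1/16 yr⁻¹ and Q10 = 1.75.
Erosion is ε = k_e·q^0.31·s·max(T, 2) with runoff q = max(P − AET, 0)
(mm yr⁻¹; bare cells evaporate nothing) and k_e calibrated once per world
so mean erosion matches 10⁻⁴ m yr⁻¹ (present-day-like); the calibrated
value is written into the run metadata.  The cation flux is
ω = χ_m·ε·(1 − exp[−K·A(T)·(1−e^(−k_w·q))·(z/ε)^(σ+1)/(σ+1)])·f_BM with
χ_m = 0.1, z = 10 m, E_a = 20 kJ mol⁻¹, T₀ = 288.15 K, K = 6·10⁻⁵,
k_w = 10⁻³, σ = −0.1, and the vegetation enhancement
f_BM = (1 − BM_norm)/6 + BM_norm, i.e. bare ground weathers at one sixth
of the fully vegetated rate (BM_norm saturates at 140 Mg C ha⁻¹).  Global
CO₂ consumption scales 10¹³ mol C yr⁻¹ by ω/ω_ref, with ω_ref the
area-integrated flux of the initial state.

## Numerical choices

* λ bisection: 60 halvings (machine precision) in the scalar API, 16 in
  the engine; height bisection 14 vs 9; height scan 6 vs 4 points.  The
  engine settings are the documented desk-scale configuration used for the
  36 × 18 step-warming experiment; all are arguments.
* DE: pop 16 × 30 generations (batch) with a 40-iteration pattern polish;
  the scalar API uses ≥24 × 60 plus the dual-axis search and a
  10-start/120-iteration polish.
* Degenerate inputs: supply below the minimum demand pins λ at its lower
  bound with AET = supply; ε = 0 gives ω = 0 by continuity; negative NPP
  clamps the soil stock to zero; competition ties break toward the taller
  candidate, in canonical cell order (permutation-invariant).

## Known limitations

Because the synthetic warming is winter-dominated everywhere, the warm
state's seasonal cycle has no exact pre-event analog anywhere on the
globe; the min-of-three niche penalty therefore keeps a residual
productivity deficit even under strong dispersal, and in this world the
warming level below which slow-evolving vegetation avoids a sustained
NPP decline sits below a 3 °C land-mean offset (the scaled-down
experiment in `tests/test_acceptance.py` documents this: at 3 °C the
late-body global NPP recovers to ~75% of the pre-event mean, versus
~20% at 8 °C).  GCM warming patterns, with near-symmetric seasonal
warming at low latitudes, are gentler in this respect.

One reference plant per cell — no coexistence, understory or demography;
no sub-10-kyr dynamics or interannual variability; no nutrient cycles,
fire or herbivory; no feedback of weathering/biomass on atmospheric CO₂
(the forcing is prescribed); the NLR reconstruction assumes trait
conservatism between fossil taxa and their living relatives, so only
relative trends are interpretable.  Passing tests on the synthetic world
show the mechanism chain (niche stress → productivity loss → dispersal-
and evolution-limited recovery → carbon and weathering response) behaves
as designed, not that magnitudes transfer to any real paleogeography.
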