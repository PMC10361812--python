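# Methods

This note documents the model equations, the default parameterization
and its rationale, the numerical scheme, and known limitations.

## Scope and coupling

The package simulates an autecological batch culture: one protist
population, one non-growing prey field, one closed water parcel.  The
biology is a 19-state ODE system (protist C/N/P/Chl/acquired capacity;
prey C/N/P/Chl; NH₄, NO₃, PO₄; DOC/DON/DOP; voided VOC/VON/VOP; and the
cumulative biological DIC change).  The carbonate system is evaluated
strictly downstream at output resolution: the biology never sees [H⁺],
so a single biological integration serves every initial-pCO₂ variant
and the variants differ only through the initial air–sea equilibrium.
DIC being far in excess of photosynthetic demand in all default
scenarios, the absence of a DIC→physiology feedback is consistent
rather than an approximation error; runs that would exhaust DIC raise
a solver error instead of silently extrapolating.

Units: biological pools in µg atom L⁻¹ (= µmol L⁻¹), chemistry in
µmol kg⁻¹, converted 1:1 (seawater density 1.025 kg L⁻¹ ignored; the
~2.5 % scale error is far below model-form uncertainty and keeps the
closed mass balance exact in one unit system).

## Carbonate chemistry

Constants: Weiss (1974) K₀; Lueker et al. (2000) K₁/K₂ (total scale);
Dickson (1990) K_B; Millero (1995) K_W; Uppström (1974) total borate.
The alkalinity balance solved for [H⁺] is

TA = [HCO₃⁻] + 2[CO₃²⁻] + [B(OH)₄⁻] + [OH⁻] − [H⁺],

omitting sulfate/fluoride association and phosphate alkalinity
(< 0.01 µmol kg⁻¹ at bloom pH; nutrient-driven TA changes are instead
carried explicitly through the charge-balance increments +1/−1/+1 per
µmol of NO₃/NH₄/PO₄ uptake).  Root finding is a bisection-safeguarded
Newton iteration on log₁₀[H⁺] inside a fixed pH 2–12 bracket, accepted
at |TA(H) − TA|/TA < 10⁻⁹; atmospheric equilibration fixes
CO₂(aq) = K₀·pCO₂ and solves the same balance by bisection.  Fidelity
is asserted against an independently coded reference calculation
(0.005 pH over DIC 1800–2400 × TA 2100–2500 µmol kg⁻¹ at 15 °C, S 35;
4 significant figures on the constants), not against formulation
identity.

## Physiology

**Quotas and controls.** Normalized quota
q_X = (X/C − X_min)/(X_max − X_min) for X ∈ {N, P}, with bounds
N/C ∈ [0.05, 0.20] and P/C ∈ [0.003, 0.02] (bracketing Redfield
0.151 and 0.0094).  Nutrient stress s = 1 − min(q_N, q_P).  Controls
are normalized Hill sigmoids c(s) = s²(1+k²)/(s²+k²) with k = 0.5:
zero when fully replete, exactly 1 at maximal stress.  Element-specific
uptake controls use the element's own quota.  Trophic priority caps the
de-prioritized control at 0.4 (equal priority: no caps), so the
favoured mode is at least as de-repressed at every nutrient status; a
threshold shift alone was tried first and discarded, because all
sigmoids saturate at full stress and the post-bloom regime — where the
priority treatments differ most in DOC production — then collapses onto
one behaviour.

Two demand terms guard against physiological dead ends that a pure
stress control would create.  (i) Gross photosynthesis is scaled by
max(photo control, min(q_N, q_P)): a replete cell fixes carbon at
capacity to supply growth, a starved cell fixes for stress-driven
overflow; without the growth-drive term a replete population shuts
down fixation, respires into its quota ceiling and dies.  (ii) The
phagotrophy control adds a carbon-stress term
q·(1 − photosynthetic competence), where competence is 1 for
constitutive types and acquired-capacity × Chl-saturation for NCMs: a
zooplankton (or an NCM with run-down photosystems) at maximum quota is
carbon-starved, not sated, and keeps feeding.

**Acquisition.**
Photosynthesis: P = 3 µ_max · (Chl:C / Chl:C_max) · (1 − e^(−PFD/75)) ·
demand · capacity · C; PFD 500 µmol m⁻² s⁻¹ is saturating (> 0.998 of
maximum), 50 is limiting (~0.49).  Chl is a carbon-equivalent index
pool relaxing (1 d⁻¹) toward min(q_N, q_P)·Chl:C_max·C for constitutive
types — starved cells shed pigment, which is what terminates overflow
production once the quota floor is reached.
Uptake: Michaelis–Menten (half-saturations 0.3 µM NH₄/NO₃, 0.1 µM PO₄)
× uptake control, V_max = 3 µ_max · quota maximum; ammonium represses
nitrate uptake multiplicatively with K_inhib = 0.5 µM, giving the
sequential DIN drawdown typical of such models.
Grazing: type-II in prey C (half-saturation 50 µM C), I_max = 3 µ_max,
encounter factor ∝ predator ESD (clearance per biomass), prey N/P/Chl
taken in stoichiometric proportion.

**Digestion.** Voided fraction 1 − AE; SDA fraction of the retained
ration released as CO₂/NH₄/PO₄; the remainder is anabolate.  Defaults
AE = 0.75 and SDA = 0.30 sit inside the observed ranges (20–40 %
voided, ~30 % SDA) and jointly yield the 1.9×/1.3×/3:1 balance-point
figures.  Effective AE is additionally scaled by √(relative prey
quality) — the worst of prey N:C and P:C against Redfield — so poor
prey is voided more (stoichiometric ecology); Redfield prey digests at
exactly the configured AE.

**Internal SDA recycling.** Element-wise,
recycled = min(SDA release, concurrent demand) with demand = gross
photosynthesis (C) or potential inorganic uptake (N, P); recycled
amounts reduce external CO₂ uptake and external nutrient uptake, the
remainder is released to the water.  A zooplankton has no demands, so
its whole SDA release is external.

**Maintenance.** Basal respiration 0.15 µ_max per biomass C (the value
that closes the 3:1 phagotrophy:fixation ratio at the balance point);
DOM leak = 0.10 × gross anabolic C input (photosynthesis plus
assimilated food — heterotrophs leak from digestion, consistent with
zooplankton recovering their leaked DOC, which re-enters biomass at
0.3 d⁻¹ for that type only), with N and P leaking in biomass proportion
gated away from the quota floor.  Quota-boundary fluxes keep the Droop
bounds invariant: carbon overflow (to DOC) engages in a 5 %-wide band
above the quota floor, NH₄/PO₄ regeneration below the ceiling, plus a
stiff (10 d⁻¹) relaxation against integrator overshoot.  Away from the
bands these fluxes are identically zero.

**Acquired phototrophy.** Capacity gains saturate toward 1 with
specific chloroplast ingestion (gain rate 2 per Chl:C_max-equivalent)
and decay exponentially: 0.7 d⁻¹ for the generalist (phototrophy fades
within ~3 days of prey exhaustion) versus 0.05 d⁻¹ for the plastidic
specialist (half-life 14 days, 14× the generalist — chosen so the
specialist keeps fixing carbon well past prey exhaustion and its DIC
drawdown exceeds the phytoplankton's, while the generalist's collapses).
Generalists only retain ingested chloroplast material; specialists
additionally photoacclimate toward capacity × quota-scaled Chl:C_max.

## Scenarios and numerics

Defaults mirror the study conditions: NH₄ 10 µM, NO₃ 10 µM, PO₄
1.25 µM; Redfield prey of 5 µm ESD at 132.5 µg atom C L⁻¹ (N 20, P
1.25), chloroplast content 10 % of prey C; PFD 500 (50 for low light)
on a 0.7:0.3 light:dark square wave; TA 2300 µmol kg⁻¹ (typical
open-coast seawater; not a printed value, exposed as a parameter);
15 °C, S 35; pCO₂ variants 300 and 600 µatm; 20 days at 0.02-day
output.  The inoculum is 0.25 µg atom C L⁻¹ at Redfield stoichiometry
(≈ 3.5 cells mL⁻¹ of 20 µm cells) — a realistic dilute inoculum,
chosen together with I_max = 3 µ_max so that grazers exhaust the prey
field near day 10 of the default run.  Constitutive types start
half-acclimated (Chl:C at half maximum); NCMs start with no
photosystems.

Integration uses LSODA (rtol 10⁻⁸, atol 10⁻¹⁰), stopped and restarted
at every light/dark boundary so the square wave is never smeared across
a step.  Because the element totals have identically zero time
derivative by construction, the multistep scheme preserves them to
near machine precision (observed closure ≤ 10⁻¹¹ relative over 20
days).  Small negative excursions are clipped at 10⁻⁶; anything larger
aborts the run.  Runs are bit-deterministic: there are no stochastic
terms.

## Proximal [H⁺]

Pure-diffusion Sherwood formulation: surface offset
Δc = −Q/(4π·D·r·Sh) per solute (D_DIC 1.2, D_NH₄ = D_NO₃ 1.5, D_PO₄
0.7 × 10⁻⁹ m² s⁻¹ at 15 °C; Sh = 1 for the non-motile reference,
larger for motile/stirred cells).  Per-cell fluxes divide population
fluxes by the abundance implied by biomass and cell carbon
(0.2 pg C µm⁻³ of biovolume).  Surface TA collects the charge-balance
weighted nutrient offsets; the surface (DIC, TA) pair is re-speciated
with the bulk constants.  Boundary-layer CO₂ hydration kinetics and
swimming hydrodynamics are not modelled, so proximal amplitudes for
large, fast cells should be read as upper bounds.

## Interpreting the synthetic scenarios

The scenario generator *is* the experiment: closed parcel, non-growing
Redfield prey, square-wave light, one population.  Real coastal blooms
add gas exchange, mixing, prey growth and community interactions, all
of which damp or restructure the signals simulated here; passing tests
therefore demonstrate the internal physiological–chemical logic (signs,
orderings, diel structure, buffering asymmetry between pCO₂ variants),
not quantitative field trajectories.  The exact functional forms of
the controls are re-derivations constrained by behaviour, so precise
event timings (e.g. the day of prey exhaustion) carry model-form
uncertainty of order ±2 days and the trajectory magnitudes (peak DOC,
final biomass) are configuration-dependent.

## Design choices made where the design was open

- Priority = cap (0.4) on the de-prioritized control rather than a
  threshold shift (rationale above).
- The prey-capture interval supports two readings of the reported
  ingestion multiple — a multiple of µ (default) or an absolute d⁻¹
  ration — selected by the ``interpretation`` flag, because the two
  differ by the factor µ and both appear in use; neither is asserted
  numerically for the 20 µm/5 µm pair.
- Zooplankton DOC recovery is implemented as slow first-order
  reabsorption by that configuration only (off for all other types).
- The carbon-flux ledger asserted in tests pairs gross photosynthesis
  with gross SDA release (equivalently, external CO₂ uptake with net
  external SDA release); pairing gross fixation with *net* external
  SDA would double-count the recycled carbon whenever recycling is
  active.

## Known limitations

- Osmotrophic DOM uptake (beyond the zooplankton bookkeeping above),
  prey growth, multiple prey types, calcification, bacterial
  degradation of DOM/VOM, diel vertical migration and any
  [H⁺]→physiology feedback are out of scope.
- The Chl pool is a carbon-equivalent index excluded from the element
  balance; absolute Chl values are not interpretable.
- Alkalinity ignores fluoride/sulfate association and pressure
  dependence; validity is bounded by the constant formulations
  (T 0–40 °C, S 20–40).
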