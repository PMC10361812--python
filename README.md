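# protistph

Protist plankton physiology coupled to seawater carbonate chemistry:
how the growth of phytoplankton, zooplankton and mixoplankton changes
bulk and near-cell [H⁺]/pH in closed coastal water parcels starting
from pre-industrial (300 µatm) versus future (600 µatm) air–sea CO₂
equilibria.

Plankton phototrophy consumes CO₂ and raises pH (basification);
heterotrophy does the converse.  Mixoplankton — protists that both
photosynthesize and eat prey in the same cell — might be expected to
buffer their own pH environment.  This package provides the tools to
test that idea *in silico*: a mass-conserving physiological flux model
of five protist functional types, a downstream seawater CO₂-system
solver, a spherical-diffusion model of the cell-surface (proximal)
[H⁺] microenvironment, and the desk arithmetic for the
phagotrophy-versus-phototrophy balance point.  It is aimed at plankton
ecologists and carbonate-chemistry modellers exploring ocean
acidification and bloom dynamics.

## The model

**Functional types.** Five configurations share one physiology
(µ_max = 0.693 d⁻¹, ESD 20 µm) and differ only in trophic capability:

| type | photosynthesis | NO₃ | NH₄ | ingestion |
|---|---|---|---|---|
| phytoplankton | constitutive | ✓ | ✓ | — |
| zooplankton | — | — | — | ✓ |
| GNCM | acquired, short-lived | — | ✓ | ✓ |
| pSNCM | acquired, maintained | ✓ | ✓ | ✓ |
| CM | constitutive | ✓ | ✓ | ✓ |

**Physiology.** Droop quota stoichiometry: internal N/C and P/C move
freely between bounds; trophic controls are sigmoids of the normalized
quota.  Ingested prey C/N/P is split into voided micro-faeces
(fraction 1 − AE), a specific-dynamic-action loss (fraction SDA of the
retained ration, released as CO₂, NH₄⁺ and PO₄) and anabolate.  Inside
a mixoplankton the SDA releases first meet the concurrent
photosynthetic CO₂ demand and nutrient demand — only the surplus
reaches the water.  Gross photosynthesis follows a saturating P–I
response scaled by Chl:C and carbon demand; maintenance comprises
basal respiration, DOM leakage, stoichiometric carbon overflow and
NH₄/PO₄ regeneration.  Every element budget closes exactly.

**Chemistry.** The water parcel is closed to gas exchange after
initial equilibration with the atmosphere.  The CO₂ system
(K₀, K₁, K₂, K_B, K_W at 15 °C, S 35; total pH scale) is solved from
DIC and total alkalinity, where biology forces

dDIC/dt = respiration + external SDA CO₂ − external photosynthetic uptake,
ΔTA = (+1)·ΔNO₃-uptake + (−1)·ΔNH₄-uptake + (+1)·ΔPO₄-uptake.

The chemistry runs strictly downstream of the biology (no [H⁺]
feedback), so nutrient and biomass dynamics are identical across pCO₂
variants and the runs isolate the carbonate-system consequences.

**Proximal [H⁺].** A cell taking up a solute at Q mol s⁻¹ depresses its
surface concentration by Q/(4π·D·r·Sh); surface DIC and TA offsets are
re-speciated to give the near-cell pH.  Larger cells (fixed
biomass-specific rates) have per-cell fluxes ∝ r³ against diffusion
∝ r, hence much larger proximal excursions.

**Balance point.** With assimilation efficiency AE and SDA fraction
lost on anabolism, a pure phagotroph growing at µ must ingest
µ/(AE·(1 − SDA)) ≈ 1.9 µ (AE 0.75, SDA 0.30).  A mixoplankton whose
gross fixation exactly offsets its respiratory CO₂ needs only
µ/AE ≈ 1.3 µ, at a phagotrophy : gross-fixation ratio of
(1/AE) / (SDA + basal) ≈ 3 : 1 with basal respiration 0.15 µ.

## Worked example

```python
import protistph as pp

# ingestion multiples at the trophic balance points
pp.balance_point(0.75, 0.30, "pure_phagotroph")          # 1.905
pp.balance_point(0.75, 0.30, "mixoplankton_zero_net_DIC")  # 1.333
pp.phago_to_fixation_ratio(0.75, 0.30, 0.15)             # 2.963

# a 20-day batch culture of constitutive mixoplankton
run = pp.run_scenario(pp.Scenario(config=pp.make_config("CM")))
for s in pp.summarize_run(run):
    print(f"p{s.pCO2_init:g}: DIC {s.DIC_initial:.0f} -> {s.DIC_final:.0f}"
          f"  pH {s.pH_initial:.3f} -> {s.pH_final:.3f}")
```

prints

```
p300: DIC 2027 -> 1584  pH 8.150 -> 8.772
p600: DIC 2150 -> 1707  pH 7.892 -> 8.619
```

The CM bloom consumes all inorganic N plus the prey field and draws
down 443 µmol kg⁻¹ of DIC in both variants; because the biology is
identical, the pH excursion is set purely by the carbonate system —
the 600-µatm water, with its weaker buffering, travels further
(+0.727 vs +0.622 pH units).  The same scenario for zooplankton gives
ΔDIC = +68 µmol kg⁻¹ and a [H⁺] *rise* that is 2.6× larger in the
600-µatm variant.

The same functionality is exposed on the command line:

```sh
protistph speciate --pco2 300 --ta 2300         # one-line JSON CO2 system
protistph run --scenario scenario.yaml --out results/
protistph calc balance --mode pure_phagotroph   # 1.9048
protistph presets --id fig5 --emit-dir scenarios/
```

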