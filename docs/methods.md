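# Methods

## Scope and structure

`dairylca` couples a cohort dairy-herd simulator, a feed land-footprint
indicator, an attributional cradle-to-farm-gate GHG inventory, and
stock-change land-use-change (LUC) accounting into a 2020–2030
scenario engine for two mixed rainfed production systems (tropical
MRT, humid MRH), each with a Traditional (indigenous cattle) and a
Modern (improved cattle) dairy sector. The public surface is
`DairySectorModel` / `SectorResults`; the submodules (`herd`, `feeds`,
`footprint`, `emissions`, `luc`, `projection`, `montecarlo`,
`synthetic`) are usable directly.

## Cow nutrition model

The cow simulator is a deliberate simplification of a full dynamic
livestock model. Monthly time steps (365/12 d); lactation starts with
the rains (November) and runs `lactation_length` days. Genetic
potential is partitioned by a flat lactation curve. In each lactation
month the daily yield is

    min( (ME − ME_maint) / 5.0 ,  (CP − CP_maint) / 0.078 ,  potential_daily )

with maintenance scaling with metabolic liveweight: ME_maint = 0.45 MJ
× LW^0.75 d⁻¹, CP_maint = 3.0 g × LW^0.75 d⁻¹. The energy cost of
5.0 MJ ME and protein cost of 78 g CP per kg FPCM are conventional
factorial values for tropical dairy cattle; all four coefficients are
configurable (`NutritionCoefficients`). Intake (DM, GE, N) accumulates
over all 12 calendar months — the cow eats year-round, lactating or
dry — which slightly overstates dry-period intake relative to a model
with body-reserve dynamics; it keeps intake, methane, and land demand
on one consistent basis.

Breed parameters: local cattle 250 kg, potential 900 kg
FPCM/lactation, 280-d lactation; improved cattle 400 kg, potential
2200 kg, 305-d lactation. Calving intervals (593.5 d local, 553.4 d
improved) are fixed by requiring the lactation→annual conversion
(×365/interval) to be internally consistent with the regional
baseline yield pairs; for improved cattle this consistent value lies
slightly above the 400–520 d range quoted in the breed literature — a
data inconsistency in the sources, resolved in favour of yield
consistency.

## Feeds and scenarios

The feed catalog carries the regional biomass and flux parameters
(reference yields: bran 0.44, cake 0.36, stover 2.18, Napier 13.10,
pasture 10.0, native grass 3.0 Mg DM/ha/yr; use efficiencies
0.50–0.95; soil N₂O fluxes 0.08–1.03 kg N₂O/ha/yr). Nutrient contents
(ME, CP, GE, digestibility) are package defaults from standard
tropical feed-composition references and are config-overridable.
Urea-molasses treated stover gets +0.04 absolute CP and +15% relative
ME over untreated stover — an assumption pending measured values.

Scenario transforms are pure diet operations composed Cn → Fo → Co:

* **Cn** substitutes treated for untreated stover in cow diets,
  DM-for-DM (other cohorts unchanged).
* **Fo** raises Napier to 25% (local) / 50% (improved) of each
  cow-month's DM offer, removing the increment from grass and pasture
  proportionally; total DM conserved. Applied year-round.
* **Co** adds 2.0/0.5 (local) or 5.0/1.5 (improved) kg DM/d of a 67%
  bran / 33% cake mix on top of the offer — the higher rate in the
  first three lactation months, the lower rate in the remaining
  lactation months, nothing while dry. Supplementation is additive,
  not substitutive.

## Land footprint

Area per feed = annual offer / (reference yield × use efficiency),
summed over cohorts × feeds and classed as maize cropland, sunflower
cropland, sown grassland (Napier), or native grassland (pasture +
grass). Maize bran and stover are co-products of one hectare: maize
area = max(bran-implied, stover-implied area); surplus co-product is
discarded, never double-counted. Because of this max rule the ledger
is exactly additive across cohorts only when the same product is
binding throughout; it is always homogeneous of degree one in offers
and head counts.

## GHG inventory

* Enteric CH₄ = GE intake × Ym / 55.65. Ym declines linearly with diet
  ME density from 0.065 at 7.5 MJ/kg DM (slope 0.0024 per MJ), floored
  at a 7.5% relative decline — a Tier-3-like stand-in for a full
  fermentation model.
* Manure: VS from GE intake, digestibility, urinary energy (4%) and
  ash (8%) per the Tier 2 form; CH₄ = VS × 365 × B0 (0.13 m³/kg) ×
  0.67 × MCF (0.02, grazing-dominated systems). N₂O = excreted N × EF3
  (0.02) × 44/28. Cow N excretion = N intake − milk N; support cohorts
  excrete 95% of intake.
* Soil N₂O: per-hectare baseline fluxes by land class (maize hectares
  use the bran-pathway flux 1.03); fertilized hectares under +Cyg add
  N rate × EF1 (0.015 kg N₂O-N/kg N) × 44/28. The printed unit of EF1
  is ambiguous between N₂O and N₂O-N; the IPCC N₂O-N convention is
  used, which also better matches the reported flux multiplication
  factors.
* Embodied CO₂ of purchased inputs: bran 0.10, cake 0.12 kg CO₂/kg;
  fertilizer N 3.5 kg CO₂/kg N. Order-of-magnitude literature values,
  config-overridable; no headline result depends on them.
* GWP100: CH₄ 28, N₂O 265.
* Mass allocation milk/(milk+meat), clipped to [0.85, 0.95]; meat from
  sex-specific culling (7.7% female, 14.0% male) at 52% dressing.
  Intensities are reported per kg FPCM, direct (excluding LUC) and
  total (including it).

Under +Cyg, fertilizer-related emissions (EF1 N₂O and embodied
fertilizer CO₂) are allocated to dairy by the mass share of the crop
hectare's output actually used as feed (bran + stover of the maize
grain+stover output; cake of the sunflower seed output). The land
footprint still counts the full hectare — it is a land-competition
indicator — but charging dairy the entire hectare's fertilizer while
the flour feeds people would misattribute the food system's inputs.

## Land-use change

Stock-change coefficients: grassland−cropland = 52.5 − 41.5 = 11.0 Mg
C/ha; native−grassland = 31.5 (MRT) / 30.9 (MRH) Mg C/ha (weighted
shrub/forest/wetland means; the weight solver `native_delta_c` is
exposed for exploration). Each converted hectare releases Δc × 44/12
Mg CO₂ amortized evenly over 20 years; every year's expansion opens
its own stream, and all streams opened in-window stay active through
2030 (their tails beyond 2030 are not reported).

Attribution is year-over-year within a run's adopted regime. The first
regime year (2020 for baselines, 2021 for scenario runs — adoption is
instantaneous and full) establishes the land base; pre-existing land
use, including any initial excess of grassland demand over
availability, is historical conversion and not attributed. Cropland
expansion beyond the run's previous peak displaces grassland 1:1;
native ecosystems convert by max(0, grassland demand + cumulative
displaced − availability), incrementally. Contraction neither emits
nor sequesters. Treating the adoption-year diet switch as physical
conversion was rejected: it charges a comparative-statics rebasing as
a one-off mega-conversion and inverts every scenario ordering the
framework is meant to measure. Gridded availability analysis is
replaced by one scalar availability per system × sector (default: 95%
of the Traditional and 98% of the Modern sector's initial grassland
demand, so the constraint binds as herds grow).

## Projection matrix

Per production system: 2 sector baselines + 2 sectors × 3 feeding
scenarios × 2 crop-yield variants = 14 runs (28 total). Scenario runs
keep the baseline herd trajectory. Feed-crop yields grow at 3.4%/yr
(maize) and 4.1%/yr (sunflower); under +Cyg they step once at adoption
by half the gap to water-limited potential (6.0 / 3.0 Mg/ha → steps of
2.27 / 0.985 Mg/ha), then continue growing at the historical rate from
the stepped level, sustained by fertilizer at 14 kg grain per kg N
(162 / 70 kg N/ha). Crop-product reference yields in the feed catalog
scale with the crop yield path.

## Uncertainty

Monte Carlo with unit-mean lognormal multipliers (positivity for
factors and yields): Ym 10%, LUC stock-change coefficients 20%, EF1
66%, EF3/B0/MCF 30%, embodied factors 20%, biomass yields 20%. Herd
counts (10%) and feed offers (5%) are uncertain only in baseline runs
— scenario inputs are defined relative to the baseline — and are
interpreted as survey-sampling uncertainty of sector means, not
farm-level dispersion (which the generator models separately; using
the dispersion as mean uncertainty lets milk collapse to zero in the
lower tail and produces unbounded intensity intervals). Intervals are
empirical 2.5/97.5 percentiles of the re-executed pipeline; default
2000 draws; draws that produce zero milk are recorded as infinite
intensity rather than discarded. (seed, draws, spec) fully determine
the output.

## Synthetic survey generator

Stands in for the unavailable farm survey. Per sector it draws
per-farm feed offers from gamma distributions (cv 0.30) around
season-specific means and uses the across-farm mean as the sector
diet, so the diet converges to the specified means as farms grow.
Defaults encode: wet-season grass/pasture-dominated diets, dry-season
stover-heavy diets, sparse concentrate use in the Traditional sector
and moderate use in the Modern sector, calibrated once so baseline
lactation yields fall in the published regional plausibility bands
(local 500–600, improved 1350–2200 kg/lactation); a 95/5 split of cows
between indigenous and improved (within the reported 90–98% indigenous
band); herd overheads larger in MRT than MRH and much larger in the
Traditional sector; support cohorts eating roughage at 2.2% of
liveweight. What it does not emulate: socio-economic strata, spatial
farm placement, intra-annual herd dynamics, or correlated survey
non-response — so green tests demonstrate internal consistency of the
pipeline under realistic magnitudes, not fidelity to any particular
survey.

Problem sizes used in the shipped tests and acceptance script — 1000
synthetic farms, the full 28-run matrix, 300–800 Monte Carlo draws,
10⁴ farms for the parameter-recovery check — were chosen as the
smallest sizes at which the sampling error of every checked statistic
is comfortably below its tolerance.

## Numerical choices and degenerate inputs

Months are uniform (365/12 d) with a fractional final lactation month.
Diets with zero offers produce zero milk and intake; runs whose total
milk is zero carry no intensities (allocation undefined) and are
reported as such. Forage substitution errors if grass+pasture cannot
absorb the Napier increment (naming the month); unknown feeds error
naming the feed. Fractional head counts are expected values, not
agents. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`.

## Known limitations

Exact reproduction of the original survey-calibrated headline
intensities is out of reach without the survey data and the full
livestock model; this package targets the arithmetic conventions
exactly and the scenario orderings directionally. Within-class land
management change (grassland degradation), forest grazing, demand
rebound, genetic-gain scenarios, post-farm-gate emissions, and
economic analysis are out of scope. The competition effect assumes
cropland always expands onto grassland; the Ym and treated-stover
uplifts are stand-ins pending measured values.
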