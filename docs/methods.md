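# Methods

`cropdrivers` decomposes the variability of simulated crop yields — and the
change of yields under climate scenarios — into contributions from mean
temperature, drought, heat stress (driven by air or canopy temperature) and
atmospheric CO2.  The decomposition rests on a factorial of six simulation
treatments in which the stress mechanisms of a generic crop simulator are
switched on and off independently, every scenario being run twice (ambient
360 ppm and an elevated CO2 level).  This note describes the model, the
synthetic study system, the numerical choices, and what the tests do and do
not establish.

## The generic crop simulator

The simulator is a daily-timestep radiation-use-efficiency model with four
coupled mechanisms.

**Phenology.**  Thermal time accumulates as
`max(0, min(Tavg, T_opt) − T_base)` per day; anthesis and maturity occur at
fixed thermal-time totals.  Warmer mean temperatures therefore shorten the
season, which is the main pathway by which mean warming reduces potential
yields (less radiation is intercepted over a shorter cycle).  Winter-cereal
vernalization and photoperiod control are not modelled; the winter-wheat
preset uses autumn sowing (day 289) together with a raised effective base
temperature (3 °C) so that anthesis in warm-winter climates falls in spring
rather than mid-winter — the standard workaround when the vernalization and
photoperiod machinery is out of scope.

**Growth.**  A leaf-area index follows thermal time (linear rise from
emergence to anthesis, linear senescence over the last 65% of grain fill);
light interception is `1 − exp(−k·LAI)`; potential growth is
`RUE × f_int × radiation × f_T`, with `f_T` a trapezoidal temperature
suitability (linear from base to optimum, linear decline above the optimum
over a 10 °C span) that stands for the balance of photosynthetic and
respiratory responses.  Yield is biomass × harvest index.

**Water.**  Transpiration demand follows a transpiration-efficiency
formulation, `demand = growth_potential × VPD / (TE_c × te_mult)`, with VPD
from the Tetens saturation curve at Tmax/Tmin minus actual vapor pressure —
the convexity of the Tetens curve is what makes atmospheric demand respond
non-linearly to warming.  Supply comes from a single soil-water bucket of
capacity TAWC from which at most a fraction `k_r = 0.1` per day is
extractable; the drought factor `f_w = supply/demand` multiplies growth.
Under the no-water-limitation treatments, automatic irrigation tops supply
up to demand, so `f_w ≡ 1` exactly.  Soil evaporation and runoff are
omitted: the bucket tracks transpiration and drainage only, which preserves
the drought signal while keeping the water account exactly closed (the test
suite verifies conservation to 1e-9 mm).

**Heat.**  Days whose driver temperature exceeds the crop's critical
threshold (31 °C for wheat, 35 °C for maize) accumulate exceedance degree
days inside a thermal-time window around anthesis; the retained fraction of
harvest index is `max(0, 1 − slope × Σ exceedance)` with slope 0.05 per
°C d.  The driver is either air Tmax or a canopy temperature
`T_air + δ_heat(1 − f_w) − δ_cool f_w` (defaults δ_heat = 5 °C,
δ_cool = 2 °C): a droughted canopy runs hotter than the air, a fully
transpiring one cooler, which is what couples drought to heat damage.  Heat
damage acts on the harvest index only; an accelerated-senescence option
(LAI growth frozen once cumulative exceedance passes a threshold) is
implemented but disabled by default, because with the senescence feedback
active heat damage perturbs the water balance and the strict treatment
orderings T1 ≥ T4 ≥ T5/T6 would hold only approximately, whereas with
HI-only damage they are exact.

**CO2.**  At concentration C, transpiration efficiency is multiplied by
`1 + γ_TE ln(C/360)` for both photosynthetic classes; RUE and maximum LAI
respond by `1 + β_RUE ln(C/360)` and `1 + λ_LAI ln(C/360)` for the C3 crop
only.  A C4 canopy is treated as CO2-saturated, so C4 potential yields are
exactly invariant to CO2 (its water-limited yields still benefit through
the TE term).  Defaults: β_RUE = 0.08, γ_TE = 0.10, λ_LAI = 0.04 — at
571 ppm these give ≈ +3.7% RUE and ≈ +4.6% TE.

## Treatments, factorial and pseudo-ensemble

The six treatments cross water limitation (off/on) with heat mode
(none / air / canopy): T1 = potential (mean-temperature effects only),
T2/T3 = heat-limited under irrigation, T4 = water-limited, T5/T6 = combined.
Each (scenario, GCM-analogue) is simulated under an ambient arm fixed at
360 ppm and an elevated arm at the scenario's CO2 level
(442/499/571 ppm for the RCP2.6/4.5/8.5 analogues).

The multi-model ensemble is emulated by multiplicative parameter jitter
around each crop preset (member 0 is the unperturbed base); the trailing
`n_air_only` members are flagged as not simulating canopy temperature, and
downstream analyses use T2/T5 instead of T3/T6 as their heat-limited and
fully limited configurations.  Structural differences between real crop
models are out of scope; the jitter is only meant to produce a plausible
between-member spread.

All rows of the factorial are independent; the batch engine steps all
seasons of a (scenario, GCM) set through the daily loop simultaneously on
flat state vectors, which is why the shipped configuration (864,000
seasons) runs in well under a minute on one CPU.

## Synthetic study system

The synthetic generators replace the gridded European climate, soil, crop
area and yield-statistics databases of the original study design.

* **Weather** is a harmonic seasonal cycle plus AR(1) daily residuals for
  temperature (stationary sd 2.5–2.8 °C, lag-1 ≈ 0.65), Bernoulli–gamma
  rainfall with monthly wet-day probabilities, a harmonic radiation cycle
  damped 20% on wet days, vapor pressure as a fixed fraction of saturation
  at Tmin (dewpoint ≈ Tmin), and Gaussian 10-m wind.  Three latitude bands
  are shipped: a cool maritime "north" (8.5 °C mean), a temperate "central"
  (10 °C) and a Mediterranean "south" (15 °C) with a pronounced summer dry
  season.  The closed-form annual mean of the generator is used by the
  Monte-Carlo tests.  What it does *not* emulate: spatial correlation
  between cells, interannual regime persistence, heat-wave clustering
  beyond AR(1), and trends within the baseline — so evaluation skill
  statistics on synthetic data say nothing about skill on real statistics;
  they verify only the machinery (de-trending, correlation, case ranking).
* **Scenarios** follow the delta-change idea: monthly temperature offsets,
  monthly precipitation factors, and explicit wet↔dry day flips with the
  ±10% radiation adjustment.  Flip days are drawn from configured monthly
  flip rates by `plan_flips` (seeded) and then applied deterministically;
  the higher-moment variability adjustments of the full enhanced
  delta-change method are out of scope.
* **Soils** satisfy FC = WP + TAWC/(10·depth); soils shallower than 40 cm
  are rejected and redrawn.  Initial water at sowing is TAWC minus 30%
  depletion of the readily available water, with RAW = 0.5 × TAWC (the
  standard depletion fraction; configurable as `raw_fraction`).
* **Observed yields** are simulated regional truth (by default the
  ensemble-median case-4 mix series) plus a linear technology trend
  (0.04 t ha⁻¹ yr⁻¹) and Gaussian noise (0.25 t ha⁻¹), floored at
  0.001 t ha⁻¹.

## Aggregation, decomposition, evaluation, sensitivity

**Aggregation** is production-area weighting: unit yield = Σ yield×area /
Σ area, with baseline areas in every scenario.  The "mix" regime pairs each
water-limited treatment with its full-irrigation counterpart (T4↔T1,
T5↔T2, T6↔T3) on the rainfed and irrigated areas respectively.

**Decomposition** (per unit, model, GCM-analogue, scenario, CO2 arm):
drought loss = 100(Yp − Ywl)/Yp, irrigated heat loss = 100(Yp − Yhl)/Yp,
rainfed heat loss = 100(Ywl − Ywh)/Yp, potential change =
100(Yp,scen − Yp,base)/Yp,base, and loss changes as percentage-point
differences.  Losses are computed from multi-year mean yields rather than
as means of annual ratios (the annual-ratio variant is available via
`annual_ratios=True`): the mean-yield order is stable when annual potential
varies strongly.  The lowest-decile subset is the ⌈n/10⌉ worst years of the
fully limited series (T6, or T5 for air-only members) of the same CO2 arm,
selected per model (ties to earlier years).  Ensemble summaries are medians
with 10th/90th percentiles across model × GCM combinations.  Drought plus
rainfed heat loss equals the combined loss 100(Yp − Ywh)/Yp by construction;
the suite asserts the identity to 1e-9 on every row.

**Evaluation** de-trends observed and simulated series by centred
moving-window anomalies: 5-year windows (t−2…t+2) in the interior, 3-year
windows at the second and penultimate years, and the available 2-year
window at the extreme endpoints (the published description leaves the
outermost year ambiguous; this choice keeps the output the same length as
the input).  A linear-trend alternative and relative anomalies are provided
as options.  Skill is the squared Pearson correlation with its t-test
p-value; significance uses α = 0.05.  The six comparison cases map to
T1, T2, T3 under irrigation and the T4/T5/T6 irrigation-share mixes.

**Sensitivity** uses main-effect and total-effect indices,
ME = var(E[Y|Xi])/var(Y) and TS = 1 − var(E[Y|X−i])/var(Y), over the
factors GCM-analogue, pseudo-model, RCP-analogue and CO2 arm, computed on
per-factor-combination EU mean yields (years averaged out first; a
replicate-inclusive variant is available).  Population variances (÷N) are
used so the finite-factorial identities are exact: ME ≤ TS, additive
models give ΣME = 1 and TS = ME, pure interactions give ME = 0, TS = 1.
Unbalanced designs (an RCP-analogue run with fewer GCM-analogues) are by
default restricted to their balanced core, with every dropped level logged;
an error policy is available.  An independent brute-force oracle
(nested-loop, no shared code) backs the implementation in the tests.

## Determinism and problem sizes

Every random choice descends from one mandatory config seed through named
`SeedSequence` paths (grid, per-cell weather, per-cell flip plans, ensemble,
observation noise), so a pipeline rerun is bit-identical; the suite compares
the CSV artifacts byte for byte.  The shipped `examples/stylized_europe.yaml`
uses 6 regions × 10 cells, 31 weather years (30 sowing seasons), baseline
plus RCP4.5/8.5 analogues × 2 GCM-analogues each, 4 pseudo-models, 6
treatments and 2 CO2 arms — 864,000 simulated seasons per run, chosen as the
smallest design that exercises every factor of the analysis with a
multi-year decile statistic.

## Demonstration: direction of change under the hot-dry analogue

From the shipped configuration (config seed 20240601; rerun with
`cropdrivers pipeline --config examples/stylized_europe.yaml --out <dir>`),
EU rainfed ensemble medians, elevated-CO2 arm, hot-dry GCM-analogue of the
RCP8.5 scenario, all years:

* grain maize: drought loss rises from 5.3% (baseline) to 19.6%
  (change +14.3 pp); rainfed heat loss rises from 0.5% to 8.4%.
* winter wheat: drought loss changes by +6.5 pp, smaller in magnitude than
  the maize response; wheat heat losses stay below 1%.
* the ambient-CO2 arm shows larger drought losses than the elevated arm
  (CO2 alleviation ≈ 1.9 pp for maize at 571 ppm).

The maize-versus-wheat contrast — drought and drought-coupled heat dominate
the maize response while wheat, maturing before midsummer, partly escapes —
is the expected qualitative behaviour for summer- versus winter-sown
cereals.

## Known limitations

* One structural model with parameter jitter cannot reproduce
  between-model structural uncertainty; the "model" sensitivity index
  quantifies jitter spread, not structural disagreement.
* No nitrogen, pests, disease, lodging or water-logging; no soil
  evaporation; no land-use change under scenarios.
* The canopy-temperature offsets are a linear proxy for an energy-balance
  calculation; only their sign structure (hotter under drought, cooler
  under transpiration) is load-bearing.
* Wheat heat losses are near zero in the shipped climate bands because the
  modelled anthesis window rarely overlaps 31 °C days; conclusions about
  heat should be read from the maize preset or from configurations with a
  later wheat anthesis.
* Synthetic observations share their generating truth with one of the
  evaluated cases; evaluation results on synthetic data are
  self-consistency checks, not skill estimates.
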