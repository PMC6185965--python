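# Stylized-Europe demonstration configuration:
# 6 regions x 10 cells each, 31 weather years (30 sowing seasons),
# baseline + 2 RCP-analogue scenarios x 2 GCM-analogues, 4 pseudo-models,
# 6 stress treatments, 2 CO2 arms per scenario.
seed: 20240601

crops: [winter_wheat, grain_maize]

grid:
  n_cells: 60
  regions:        # region -> climate band of the weather generator
    NO: north
    DK: central
    DE: central
    FR: central
    ES: south
    IT: south
  irrigated_fraction:
    NO: 0.02
    DK: 0.04
    DE: 0.05
    FR: 0.15
    ES: 0.45
    IT: 0.35
  area_scale_ha: 10000

weather:
  n_years: 31
  start_year: 1980

scenarios:
  - id: rcp45_analogue
    co2: 499
    gcms:
      warm_wet:
        dt_winter: 2.2
        dt_summer: 1.8
        p_winter: 1.08
        p_summer: 0.97
        wet_to_dry_summer: 0.03
        dry_to_wet_winter: 0.03
      hot_dry:
        dt_winter: 2.0
        dt_summer: 3.2
        p_winter: 0.95
        p_summer: 0.70
        wet_to_dry_summer: 0.12
        dry_to_wet_winter: 0.0
  - id: rcp85_analogue
    co2: 571
    gcms:
      warm_wet:
        dt_winter: 3.6
        dt_summer: 3.0
        p_winter: 1.12
        p_summer: 0.95
        wet_to_dry_summer: 0.05
        dry_to_wet_winter: 0.05
      hot_dry:
        dt_winter: 3.2
        dt_summer: 4.8
        p_winter: 0.92
        p_summer: 0.55
        wet_to_dry_summer: 0.18
        dry_to_wet_winter: 0.0

ensemble:
  n_models: 4
  n_air_only: 1   # last member falls back to air temperature for heat stress

observed:
  truth_case: 4       # synthetic observations built from the case-4 mix truth
  trend_slope: 0.04   # t/ha per year technology trend
  noise_sd: 0.25      # t/ha statistical noise

analysis:
  alpha: 0.05
  raw_fraction: 0.5
  detrend: moving
  sensitivity_treatment: T6
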