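# Observation CSV schema

One row per site-condition record; header row required; UTF-8, RFC 4180,
`.` decimal separator; missing values are empty fields. Foreign headers can
be mapped onto these names with the `column_map` argument of
`read_observations`.

| column | type | unit / vocabulary |
|---|---|---|
| site_id | string (mandatory) | opaque identifier |
| latitude | float | degrees, −90..90 |
| longitude | float | degrees, −180..180 |
| elevation | float | m above sea level |
| climate | enum | continental, temperate, arid, tropical, unknown |
| land_use | enum | agriculture, natural_forest, urban, wetland, unknown |
| trophic_state | enum | oligotrophic, mesotrophic, eutrophic, hypereutrophic, unknown |
| soil_type | enum | mineral, organic, unknown |
| hydro_regime | enum | perennial, nonperennial_wet, nonperennial_dry, unknown |
| vegetation | enum | present, absent, unknown |
| method | enum | floating_chamber, dissolved_concentration, unknown |
| co2_flux | float | g CO₂ m⁻² yr⁻¹, signed (emission > 0) |
| n2o_flux | float | g N₂O m⁻² yr⁻¹, signed |
| ch4_diffusive | float | g CH₄ m⁻² yr⁻¹, signed |
| ch4_ebullitive | float | g CH₄ m⁻² yr⁻¹, ≥ 0 |
| do | float | dissolved oxygen, mg L⁻¹ |
| ph | float | unitless |
| ec | float | electrical conductivity, µS cm⁻¹ |
| doc | float | dissolved organic carbon, mg L⁻¹ |
| tp | float | total phosphorus, µg L⁻¹ |
| tn | float | total nitrogen, µg L⁻¹ |
| chl_a | float | chlorophyll-a, µg L⁻¹ |
| no3_n | float | nitrate-N, mg L⁻¹ |
| cn_ratio | float | unitless |
| width | float | m |
| depth | float | m |
| velocity | float | m s⁻¹ |
| discharge | float | m³ s⁻¹ |
| mat | float | mean annual temperature, °C |
| map_mm | float | mean annual precipitation, mm yr⁻¹ |
| daily_flux_value | float | pre-harmonization reported rate |
| daily_flux_unit | enum | see unit vocabulary below |
| daily_flux_gas | enum | CO2, N2O, CH4 |
| season_length_days | int | 1..365, ice-free season (absent → 365-day annualization) |
| daytime_only | bool | true/false — measurement covered daytime only |

## Flux unit vocabulary

Recognized values of `daily_flux_unit` (and the `unit` argument of
`harmonize.to_gas_mass`):

`g_gas_m2_d`, `mg_gas_m2_d`, `g_gas_m2_yr`, `mg_gas_m2_yr`,
`mol_gas_m2_d`, `mmol_gas_m2_d`, `umol_gas_m2_d`,
`g_element_m2_d`, `mg_element_m2_d`, `g_element_m2_yr`

`element` units are mass of C (CO₂, CH₄) or N (N₂O); `mol` units are moles
of gas. The time basis (`_d` / `_yr`) decides whether annualization
applies.
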