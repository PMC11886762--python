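global:
  ditch_area_ha: 5353000.0
  ditch_area_range_ha:
  - 1420000.0
  - 10700000.0
  frac_ditch: 0.03
  frac_ditch_range:
  - 0.01
  - 0.05
  budgets:
    anthropogenic_co2: 11100.0
    inland_water_co2: 3900.0
    anthropogenic_n2o: 6.5
    inland_water_n2o: 0.5
  night_correction_factor: 1.27
gwp:
  gwp100:
    CO2: 1.0
    CH4: 27.0
    N2O: 273.0
  sgwp100:
    CO2: 1.0
    CH4: 45.0
    N2O: 270.0
  sgcp100:
    CO2: 1.0
    CH4: 203.0
    N2O: 349.0
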