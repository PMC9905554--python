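{
 "name": "palbociclib",
 "formula": "C24H29N7O2",
 "molar_mass": 447.543,
 "melt_temperature": 545.19,
 "fusion_enthalpy": 23.7,
 "critical_temperature": 1254.31,
 "critical_pressure": 1.6069,
 "acentric_factor": 0.466,
 "solid_molar_volume": 303.85,
 "lambda_max": 265.0
}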