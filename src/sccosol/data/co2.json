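{
 "molar_mass": 44.01,
 "critical_temperature": 304.21,
 "critical_pressure": 7.383,
 "acentric_factor": 0.2236
}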