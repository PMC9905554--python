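"""Physical constants and solvent property defaults.

Everything here is a plain module-level value so that a user who needs a
different CO2 property set (or gas constant convention) can override it in
one place.
"""

#: Ideal gas constant, J mol^-1 K^-1.
R_GAS = 8.314462

#: Atmospheric reference pressure, Pa.
P_ATM = 101_325.0

#: IUPAC 2021 standard atomic weights (abridged), g mol^-1.
ATOMIC_WEIGHTS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998403163,
    "P": 30.973761998,
    "S": 32.06,
    "Cl": 35.45,
    "Br": 79.904,
    "I": 126.90447,
}

#: Carbon dioxide pure-component constants (standard literature values;
#: molar mass g/mol, critical temperature K, critical pressure MPa,
#: acentric factor).
CO2_MOLAR_MASS = 44.01
CO2_CRITICAL_TEMPERATURE = 304.21
CO2_CRITICAL_PRESSURE = 7.383
CO2_ACENTRIC_FACTOR = 0.2236
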