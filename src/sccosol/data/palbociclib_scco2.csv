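temperature_K,pressure_MPa,co2_density_kg_m3,mole_fraction,mass_solubility_g_L,std_y,expanded_uncertainty_y
308,12.0,769,3.91000e-06,0.0305765,1.20000e-07,2.70000e-07
308,15.0,817,5.01000e-06,0.0416241,2.40000e-07,5.30000e-07
308,18.0,849,5.52000e-06,0.0476576,2.10000e-07,4.70000e-07
308,21.0,875,6.27000e-06,0.0557907,1.10000e-07,3.40000e-07
308,24.0,896,6.97000e-06,0.0635078,1.20000e-07,3.60000e-07
308,27.0,914,9.14000e-06,0.0849532,2.10000e-07,5.60000e-07
318,12.0,661,2.21000e-06,0.0148552,1.00000e-07,2.20000e-07
318,15.0,744,3.49000e-06,0.0264048,1.50000e-07,3.30000e-07
318,18.0,791,4.19000e-06,0.0337036,1.20000e-07,3.00000e-07
318,21.0,824,7.38000e-06,0.0618401,1.10000e-07,3.80000e-07
318,24.0,851,8.60000e-06,0.0744244,1.30000e-07,4.30000e-07
318,27.0,872,1.24200e-05,0.110135,4.10000e-07,9.60000e-07
328,12.0,509,1.10000e-06,0.0056937,4.00000e-08,9.00000e-08
328,15.0,656,2.10000e-06,0.014009,4.00000e-08,1.20000e-07
328,18.0,725,2.81000e-06,0.0207171,1.30000e-07,3.00000e-07
328,21.0,769,8.40000e-06,0.065689,1.90000e-07,5.30000e-07
328,24.0,802,9.72000e-06,0.0792735,2.10000e-07,5.90000e-07
328,27.0,829,1.46800e-05,0.123757,3.20000e-07,9.10000e-07
338,12.0,388,8.10000e-07,0.00319595,3.00000e-08,7.00000e-08
338,15.0,557,1.37000e-06,0.00775996,2.00000e-08,7.00000e-08
338,18.0,652,2.11000e-06,0.0139899,3.00000e-08,1.10000e-07
338,21.0,710,9.81000e-06,0.0708296,4.10000e-07,9.30000e-07
338,24.0,751,1.19700e-05,0.0914161,1.10000e-07,5.70000e-07
338,27.0,783,2.02700e-05,0.161402,9.10000e-07,2.02000e-06
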