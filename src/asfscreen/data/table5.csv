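complex_id,donors,dipole_debye,d1,d2,d3,d4,d5,d6,area_A2,volume_A3,molar_mass,energy_J,charge,abl_printed,dv_printed,asf_printed,flags
dis.h2o-01,"H2O,O2,O3,O6,O8,N1",14.47,2.559,2.091,2.051,2.237,2.038,2.118,704.04,674.36,666.656,787597.4,1,2.1823,0.0215,1.1878e-05,
dis.h2o-02,"O1,O2,O3,H2O,O8,N1",13.73,2.003,2.122,2.009,2.547,2.094,1.995,706.77,675.37,667.664,685588.1,1,2.1283,0.0203,1.0628e-05,
dis.h2o-03,"H2O,O2,O3,O4,O5,O6",13.57,2.554,2.35,2.141,2.446,2.203,2.213,690.23,669.93,664.64,814118.9,1,2.3178,0.0203,1.3906e-05,
dis.h2o-04,"O1,O2,O3,H2O,O5,O6",11.64,2.237,2.217,2.001,2.53,2.111,2.117,692.78,669.6,665.648,614768.0,1,2.2022,0.0174,1.1631e-05,
dis.h2o-05,"O1,O2,O3,H2O,O5,O8",26.1,2.049,2.085,2.018,2.537,2.211,2.198,699.71,675.36,667.664,820896.2,1,2.183,0.0386,6.866e-06,
dis.h2o-06,"H2O,O2,O3,O6,O7,N1",27.13,2.532,2.071,2.132,2.01,2.392,2.063,699.23,670.7,665.648,1155916.0,1,2.2,0.0405,9.3734e-06,
dis.h2o-07,"O1,O2,O3,O4,O8,H2O",21.48,1.933,2.434,1.962,2.366,2.267,2.519,712.92,676.72,667.664,1109704.3,1,2.2468,0.0317,1.1608e-05,
dis.h2o-08,"H2O,O3,O4,O7,O8,N1",13.61,2.524,2.074,2.055,2.286,2.047,2.136,709.82,676.42,667.664,801772.3,1,2.187,0.0201,1.2884e-05,
dis.h2o-09,"O1,O3,O4,H2O,O8,N1",14.1,2.015,2.108,2.011,2.533,1.981,2.003,710.93,676.08,667.664,865660.4,1,2.1085,0.0209,1.2945e-05,
dis.h2o-10,"H2O,O3,O4,O5,O7,O8",26.56,2.552,2.39,2.322,2.244,2.155,2.1,696.62,677.37,667.664,1399399.8,1,2.2938,0.0392,1.2086e-05,
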