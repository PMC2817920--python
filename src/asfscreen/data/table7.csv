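complex_id,donors,dipole_debye,d1,d2,d3,d4,d5,d6,area_A2,volume_A3,molar_mass,energy_J,charge,abl_printed,dv_printed,asf_printed,flags
hali.h2o-01,"O1,O3,O5,O6,O7,H2O",16.96,2.638,1.88,2.472,2.211,2.582,2.659,971.93,1085.69,1167.57,3103.006,1,2.407,0.0156,4.4e-08,
hali.h2o-02,"O2,O3,O6,O7,O10,H2O",17.89,2.557,2.128,1.948,2.512,2.394,2.301,952.2,1080.52,1185.57,-1780.23,1,2.307,0.0166,-2.3e-08,
hali.h2o-03,"O1,O2,O3,O7,O10,H2O",10.73,2.327,2.455,5.367,2.59,2.054,2.498,982.86,1086.39,1185.57,-2600.84,1,2.382,0.0099,-5.8e-08,abl_inconsistent
hali.h2o-04,"O2,O3,O5,O6,O7,H2O",16.77,2.498,1.848,1.993,2.314,2.453,2.498,966.88,1082.15,1118.57,-125.424,1,2.27,0.0155,-1.7e-09,abl_inconsistent
hali.h2o-05,"O15,O16,O17,O18,O19,H2O",14.25,2.511,2.535,2.483,2.151,2.25,1.997,1057.85,1095.69,1185.57,2657.263,1,2.32,0.013,4.33e-08,abl_inconsistent
hali.h2o-06,"O14,O16,O17,O18,O19,H2O",15.12,2.492,2.631,2.618,2.268,2.154,1.997,1047.75,1093.53,1185.57,2512.387,1,2.36,0.0138,3.92e-08,
hali.h2o-07,"O1,O16,O17,O18,O19,H2O",13.27,2.572,2.516,2.533,2.088,2.386,2.033,1020.44,1089.88,1185.57,2201.572,1,2.35,0.0122,3.9e-08,abl_inconsistent
hali.h2o-08,"O1,O14,O16,O18,O19,H2O",19.5,2.574,2.642,2.701,2.558,2.104,1.951,1009.1,1085.79,1185.57,2320.397,1,2.42,0.0178,2.88e-08,abl_inconsistent
hali.h2o-09,"O15,O16,O17,O18,O19,H2O",16.02,2.51,2.538,2.484,2.149,2.259,2.0,1057.95,1095.55,1185.57,2657.028,1,2.323,0.0146,3.85e-08,
hali.h2o-10,"O1,O16,O17,O18,O19,H2O",12.83,2.562,1.955,2.553,2.239,2.221,2.017,1023.6,1090.34,1185.57,2189.281,1,2.258,0.0118,3.85e-08,
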