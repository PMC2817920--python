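complex_id,donors,dipole_debye,d1,d2,d3,d4,d5,d6,area_A2,volume_A3,molar_mass,energy_J,charge,abl_printed,dv_printed,asf_printed,flags
kah.h2o-01,"H2O,N1,N2,O5,O6,O7",19.52,2.438,2.332,2.55,1.946,2.225,2.002,1535.1,1564.71,1549.71,1280000.0,1,2.2488,0.012475,1.48e-05,
kah.h2o-02,"H2O,O6,O7,N1,N2,N3",13.76,2.479,2.121,2.477,2.556,2.446,1.966,1570.3,1565.01,1548.71,864000.0,1,2.3408,0.008792,1.47e-05,
kah.h2o-03,"H2O,O2,O3,N4,N5,N6",27.44,2.427,2.373,2.44,2.58,1.906,2.085,1574.0,1566.24,1548.71,1770000.0,1,2.3018,0.017519,1.48e-05,
kah.h2o-04,"H2O,N4,N6,O2,O4,O6",23.48,2.535,2.147,2.017,1.972,2.147,1.995,1588.7,1566.91,1549.71,1120000.0,1,2.1355,0.014984,1.02e-05,
kah.h2o-05,"H2O,O4,O6,N2,N4,N6",15.97,2.424,2.362,2.437,2.56,1.978,1.947,1576.2,1567.12,1548.71,852000.0,1,2.2847,0.01019,1.22e-05,
kah.h2o-06,"H2O,O10,O12,N12,N13,N14",23.74,2.379,2.587,2.135,2.268,2.297,2.5,1558.6,1564.31,1548.71,1230000.0,1,2.361,0.01517,1.22e-05,
kah.h2o-07,"H2O,O10,O11,N12,N13,N14",25.02,2.198,2.082,2.58,2.281,2.253,2.542,1524.4,1562.13,1548.71,1380000.0,1,2.3227,0.016016,1.28e-05,
kah.h2o-08,"H2O,O10,N11,N12,N13,N14",36.57,2.131,2.588,2.504,2.262,2.405,2.555,1563.9,1565.28,1547.7,1560000.0,1,2.4075,0.023363,1.02e-05,
kah.h2o-09,"H2O,O10,O11,N11,N12,N14",20.9,2.126,1.923,2.338,2.494,2.602,2.526,1534.3,1561.66,1548.71,1300000.0,1,2.3348,0.013383,1.45e-05,
kah.h2o-10,"H2O,O10,O11,N11,N12,N13",22.12,2.347,1.958,2.461,2.102,2.377,2.568,1559.1,1532.94,1548.71,1140000.0,1,2.3022,0.014429,1.19e-05,
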