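species,area_A2,volume_A3,dipole_debye,dv,abl_A,energy_J,asf_best,asf_mean,n
Fe-Hali,949.7,1065.0,8.82,0.011,2.627,6307365,-6.34e-05,0.000253,50
Fe-Hali-H2O,991.7,1087.2,13.83,0.0126,2.483,3946000,8.6e-07,-5.77e-08,50
Hali,1036.5,1071.7,2.48,0.0023,,1491027,,,1
Fe-Disco,656.4,650.6,6.48,0.01,2.231,1787000,1.53e-05,0.00389,50
Fe-Disco_H2O,697.2,673.2,10.68,0.0159,2.211,1090000,6.86e-06,2.81e-05,50
Disco,689.9,650.9,4.84,0.0074,,135515,,,1
Fe-Kah,1537.0,1546.6,15.99,0.0103,2.283,2005200,1.246e-05,0.00156,50
Fe-Kah-H2O,1565.9,1565.1,19.04,0.0121,2.325,1551000,1.988e-05,3.406e-06,50
Kah,1584.3,1548.0,4.82,0.0031,,853007,,,1
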