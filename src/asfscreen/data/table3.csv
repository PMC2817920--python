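complex_id,donors,dipole_debye,d1,d2,d3,d4,d5,d6,area_A2,volume_A3,molar_mass,energy_J,charge,abl_printed,dv_printed,asf_printed,flags
kah-01,"N1,N2,N3,O5,O6,O7",18.04,2.499,2.117,2.519,2.015,2.237,2.037,1507.1,1542.8,1530.69,1160000.0,1,2.2373,0.01169,1.44e-05,
kah-02,"N3,N4,N5,N6,N7,O1",22.96,2.409,2.54,2.338,2.537,2.576,2.046,1570.5,1549.5,1528.68,1931000.0,1,2.4077,0.01482,2.03e-05,
kah-03,"N4,N5,N6,N7,O1,O2",20.38,2.472,2.043,2.435,2.463,1.962,2.305,1568.9,1551.6,1529.68,1785000.0,1,2.28,0.01313,2e-05,
kah-04,"N3,N4,N5,N6,N7,O2",25.59,2.478,2.515,2.232,2.315,2.543,2.046,1554.4,1548.7,1528.68,1854000.0,1,2.3548,0.01652,1.71e-05,
kah-05,"N4,N5,N6,N7,O2,O3",23.16,2.492,2.121,2.418,2.53,2.076,2.04,1562.0,1549.3,1529.68,1691000.0,1,2.2795,0.01495,1.66e-05,
kah-06,"N6,N7,O2,O3,O4,O5",23.35,2.499,2.547,2.29,2.102,2.482,1.851,1501.7,1540.1,1531.7,2055000.0,1,2.2952,0.01516,2.02e-05,
kah-07,"N2,N4,N6,O2,O4,O6",19.82,2.497,2.451,2.111,2.153,1.991,1.94,1564.3,1548.3,1530.69,1128000.0,1,2.1905,0.0128,1.25e-05,
kah-08,"O10,O11,O12,O13,N13,N14",19.94,2.363,2.326,2.46,1.971,2.512,2.458,1513.3,1542.8,1531.7,1686000.0,1,2.3483,0.01292,1.99e-05,
kah-09,"O10,O11,O12,N12,N13,N14",20.68,2.36,2.17,2.085,2.396,2.26,2.487,1485.6,1540.3,1530.69,1316000.0,1,2.293,0.01343,1.46e-05,
kah-10,"N11,N12,N13,N14,O10,O11",19.99,2.337,2.012,2.288,2.465,2.157,2.457,1513.9,1543.0,1529.68,1262000.0,1,2.286,0.013,1.44e-05,
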