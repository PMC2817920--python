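complex_id,donors,dipole_debye,d1,d2,d3,d4,d5,d6,area_A2,volume_A3,molar_mass,energy_J,charge,abl_printed,dv_printed,asf_printed,flags
dis-01,"O1,O2,O3,O4,O5,O6",11.17,1.957,2.485,1.964,2.456,2.184,2.253,657.4,647.87,646.625,1073380.93,1,2.2165,0.0172,2.1299e-05,
dis-02,"O1,O2,O3,O4,O5,N1",11.15,1.932,2.471,1.978,2.47,2.253,2.396,650.0,647.51,646.425,1423974.61,1,2.25,0.0172,2.8734e-05,
dis-03,"O1,O2,O3,O4,O8,N1",8.12,1.9,2.415,1.999,2.412,2.022,2.005,676.4,654.77,648.641,1131756.1,1,2.1255,0.0124,2.9625e-05,
dis-04,"O1,O2,O3,O4,O5,O8",15.76,2.228,2.444,1.945,2.232,2.208,2.269,660.4,654.66,648.641,1538512.45,1,2.221,0.0241,2.1682e-05,
dis-05,"O1,O2,O3,O6,O7,N1",12.86,2.425,2.023,2.015,1.984,2.476,2.16,661.2,649.79,647.633,1456789.72,1,2.1805,0.0198,2.4701e-05,
dis-06,"O1,O2,O3,O5,O8,N1",7.81,2.068,2.051,2.036,2.106,1.965,2.109,656.3,653.23,648.641,888909.63,1,2.0558,0.012,2.34e-05,
dis-07,"O1,O3,O4,O6,O8,N1",9.38,1.899,1.883,1.968,2.148,1.904,1.911,655.4,650.65,648.641,643672.84,1,1.9522,0.0144,1.3396e-05,
dis-08,"O1,O3,O4,O7,O8,N1",15.09,2.181,2.128,1.98,2.439,2.036,2.06,667.7,655.45,649.649,1124527.4,1,2.1373,0.023,1.5928e-05,
dis-09,"O1,O3,O4,O5,O7,O8",16.44,2.418,2.353,2.21,2.249,2.427,2.079,659.5,656.48,649.649,1723667.0,1,2.2893,0.025,2.4003e-05,
dis-10,"O1,O2,O3,O6,O8,N1",10.78,2.018,2.122,2.027,2.185,2.043,2.049,670.6,654.56,648.641,795760.82,1,2.074,0.0165,1.531e-05,
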