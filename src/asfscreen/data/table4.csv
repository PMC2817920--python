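complex_id,donors,dipole_debye,d1,d2,d3,d4,d5,d6,area_A2,volume_A3,molar_mass,energy_J,charge,abl_printed,dv_printed,asf_printed,flags
hali-01,"O1,O2,O3,O5,O6,O7",13.87,2.639,2.647,2.574,2.453,2.684,2.706,945.71,1060.93,1167.57,3674624.0,1,2.617,0.01307,6.9e-05,
hali-02,"O3,O5,O6,O7,O9,O10",19.67,2.54,2.488,2.664,2.71,2.697,2.727,1030.39,1080.05,1167.57,7393466.0,1,2.194,0.01821,8e-05,abl_inconsistent;asf_inconsistent
hali-03,"O1,O3,O5,O6,O7,O9",15.91,2.682,2.54,2.462,2.695,2.71,2.683,941.03,1069.44,1167.57,6085918.0,1,2.629,0.09596,0.0001,dv_inconsistent
hali-04,"O1,O2,O3,O6,O7,O10",19.94,2.717,2.718,2.664,2.73,2.68,2.686,893.96,1051.35,1167.57,-4685181.0,1,2.699,0.01897,-6.3e-05,
hali-05,"O2,O5,O7,O9,O10,O12",7.55,2.729,2.769,2.75,2.782,2.592,2.729,930.78,1057.96,1167.57,6953.642,1,2.72,0.00714,2.5e-07,abl_inconsistent
hali-06,"O1,O3,O5,O6,O7,O10",18.78,2.673,2.528,2.526,2.725,2.728,,1016.45,1076.59,1167.57,7292712.0,1,2.649,0.01744,0.0001,incomplete_distances;abl_inconsistent;asf_inconsistent
hali-07,"O2,O3,O5,O6,O7,O14",8.6,2.724,2.482,2.586,2.71,2.719,2.772,887.65,1046.5,1167.57,1394772.0,1,2.666,0.00822,4.3e-05,
hali-08,"O14,O15,O16,O17,O18,O19",11.75,2.687,1.886,2.614,2.318,2.219,1.999,1027.22,1076.81,1166.57,2559699.0,1,2.287,0.01091,5e-05,
hali-09,"O1,O14,O16,O17,O18,O19",11.31,2.634,2.692,2.699,2.401,2.084,1.946,976.65,1065.9,1166.6,3294402.0,1,2.416,0.01061,7e-05,abl_inconsistent
hali-10,"O1,O15,O16,O17,O18,O19",10.84,2.613,2.502,2.616,2.103,2.255,1.984,991.43,1071.33,1166.57,3577592.0,1,2.059,0.01012,6.8e-05,abl_inconsistent
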