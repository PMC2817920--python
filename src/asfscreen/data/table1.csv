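name,dipole_debye,volume_A3,dv,flags
Water,1.74,19.24,0.09,
Methanol,1.54,40.66,0.038,
Ethanol,1.48,59.08,0.025,
1-Propanol,1.59,77.37,0.02,dv_inconsistent
1-Butanol,1.6,95.69,0.017,
1-Pentanol,1.41,114.06,0.012,
1-Octanol,1.62,168.95,0.0096,
Hexane,0.0,124.8,0.0,
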