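toy_donors (synthetic amino-polyol test structure)
     RDKit          3D

 18 17  0  0  0  0  0  0  0  0999 V2000
   -3.1498    2.4460   -0.1619 O   0  0  0  0  0  0  0  0  0  0  0  0
   -3.8672    1.2252   -0.2622 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.5024    0.2924    0.8945 C   0  0  0  0  0  0  0  0  0  0  0  0
   -4.1772   -0.9734    0.7822 O   0  0  0  0  0  0  0  0  0  0  0  0
   -1.9871    0.0295    1.0550 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.8333   -1.1047    1.9416 O   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2128   -0.2524   -0.2556 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.8116   -1.3474   -0.9678 O   0  0  0  0  0  0  0  0  0  0  0  0
    0.2774   -0.5947    0.0105 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.3629   -1.8490    0.7122 O   0  0  0  0  0  0  0  0  0  0  0  0
    1.0854   -0.7030   -1.3103 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.5798   -1.7859   -2.1201 O   0  0  0  0  0  0  0  0  0  0  0  0
    2.6038   -0.9733   -1.1356 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.8344   -2.1688   -0.3614 O   0  0  0  0  0  0  0  0  0  0  0  0
    3.4271    0.1449   -0.4696 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.0955    0.2356    0.9256 O   0  0  0  0  0  0  0  0  0  0  0  0
    3.2547    1.5232   -1.1279 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.0715    2.5470   -0.4622 N   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  1  0
  3  5  1  0
  5  6  1  0
  5  7  1  0
  7  8  1  0
  7  9  1  0
  9 10  1  0
  9 11  1  0
 11 12  1  0
 11 13  1  0
 13 14  1  0
 13 15  1  0
 15 16  1  0
 15 17  1  0
 17 18  1  0
M  END
$$$$
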