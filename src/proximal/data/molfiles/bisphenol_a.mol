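bisphenol_a
     RDKit          2D

 17 18  0  0  0  0  0  0  0  0999 V2000
    1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7500    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7500   -1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500   -1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5000    2.5981    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    1.5000   -2.5981    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.7990   -1.8481    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.2010   -3.3481    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.2500   -3.8971    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5000   -5.1962    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.2500   -6.4952    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.7500   -6.4952    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.5000   -5.1962    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.7500   -3.8971    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.5000   -7.7942    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  6  1  2  0
  1  2  1  0
  2  3  2  0
  3  4  1  0
  4  5  2  0
  5  6  1  0
  3  7  1  0
  6  8  1  0
  8  9  1  0
  8 10  1  0
  8 11  1  0
 11 12  2  0
 12 13  1  0
 13 14  2  0
 14 15  1  0
 15 16  2  0
 16 11  1  0
 14 17  1  0
M  END
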