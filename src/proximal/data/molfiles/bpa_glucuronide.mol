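bpa_glucuronide
     RDKit          2D

 29 31  0  0  0  0  0  0  0  0999 V2000
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
   -0.7500    3.8971    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500    3.8971    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    1.5000    5.1962    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.0000    5.1962    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.7500    3.8971    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    3.7500    6.4952    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500    6.4952    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5000    7.7942    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7500    6.4952    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5000    7.7942    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5000    5.1962    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.0000    5.1962    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
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
 18 19  1  0
 19 20  1  0
 20 21  1  0
 21 22  2  0
 21 23  1  0
 20 24  1  0
 24 25  1  0
 24 26  1  0
 26 27  1  0
 26 28  1  0
 28 29  1  0
 28 18  1  0
  7 18  1  0
M  END
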