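benzene_oxide_gsh
     RDKit          2D

 27 27  0  0  0  0  0  0  0  0999 V2000
    3.0000    0.0000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500   -1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7500   -1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7500    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5000    2.5981    0.0000 S   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500    3.8971    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5000    5.1962    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.0000    5.1962    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
    3.7500    6.4952    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.0000    7.7942    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    5.2500    6.4952    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    6.0000    7.7942    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    7.5000    7.7942    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    8.2500    6.4952    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
    8.2500    9.0933    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    9.7500    9.0933    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    7.5000   10.3923    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500    6.4952    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7500    6.4952    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    1.5000    7.7942    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500    9.0933    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5000   10.3923    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500   11.6913    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    3.0000   10.3923    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  2  0
  4  5  1  0
  5  6  2  0
  6  7  1  0
  7  2  1  0
  8  9  1  0
  9 10  1  0
 10 11  1  0
 11 12  1  0
 12 13  2  0
 12 14  1  0
 14 15  1  0
 15 16  1  0
 16 17  1  0
 16 18  1  0
 18 19  2  0
 18 20  1  0
 10 21  1  0
 21 22  2  0
 21 23  1  0
 23 24  1  0
 24 25  1  0
 25 26  2  0
 25 27  1  0
  7  8  1  0
M  END
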