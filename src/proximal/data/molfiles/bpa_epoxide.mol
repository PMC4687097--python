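bpa_epoxide
     RDKit          2D

 18 20  0  0  0  0  0  0  0  0999 V2000
   -0.4330    0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.4330   -0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.7321   -1.5000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.0311   -0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.0311    0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.7321    1.5000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.7321   -3.0000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
   -1.7321    3.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.2321    3.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.2321    3.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.7321    4.5000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.4330    5.2500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.4330    6.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.7321    7.5000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.0311    6.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.0311    5.2500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.7321    9.0000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    0.8660    0.0000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  6  1  1  0
  1  2  1  0
  2  3  1  0
  3  4  2  0
  4  5  1  0
  5  6  2  0
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
  1 18  1  0
  2 18  1  0
M  END
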