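antipyrine
     RDKit          2D

 14 15  0  0  0  0  0  0  0  0999 V2000
   -0.5773   -4.2803    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    1.5000   -2.5981    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
    2.9918   -2.7549    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
    3.3037   -4.2221    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.8899   -3.9684    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500   -1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.0046   -4.9721    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.9955   -1.6402    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.6740   -4.8322    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7500    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7500    1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7500   -1.2990    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  5  1  2  0
  2  3  1  0
  3  4  1  0
  4  7  2  0
  7  5  1  0
  5  2  1  0
  3  8  1  0
  4  9  1  0
  2  6  1  0
  6 10  2  0
 10 11  1  0
 11 12  2  0
 12 13  1  0
 13 14  2  0
 14  6  1  0
M  END
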