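VV  locuskit synthetic demonstration matrices
XX
//
ID  M_MEF2_SYN
BF  MEF2
DE  synthetic consensus-derived matrix (CTAAAAATAG-like A/T core)
P0      A      C      G      T
01      5      80     5      10      C
02      10     5      5      80      T
03      80     5      5      10      A
04      50     5      5      40      W
05      80     5      5      10      A
06      80     5      5      10      A
07      80     5      5      10      A
08      10     5      5      80      T
09      80     5      5      10      A
10      5      5      80     10      G
XX
//
ID  M_MYOD_SYN
BF  MYOD
DE  synthetic E-box (CAGCTG) matrix
P0      A      C      G      T
01      5      85     5      5      C
02      85     5      5      5      A
03      5      5      85     5      G
04      5      85     5      5      C
05      5      5      5      85     T
06      5      5      85     5      G
XX
//
ID  M_SRF_SYN
BF  SRF
DE  synthetic CArG box (CCATATATGG) matrix
P0      A      C      G      T
01      5      80     5      10      C
02      5      80     5      10      C
03      80     5      5      10      A
04      10     5      5      80     T
05      80     5      5      10      A
06      10     5      5      80     T
07      80     5      5      10      A
08      10     5      5      80     T
09      5      5      80     10      G
10      5      5      80     10      G
XX
//
ID  M_CEBP_SYN
BF  C/EBP
DE  synthetic TTGCGCAA-like matrix
P0      A      C      G      T
01      5      5      10     80     T
02      5      5      10     80     T
03      10     5      80     5      G
04      5      80     5      10     C
05      10     5      80     5      G
06      5      80     5      10     C
07      80     5      5      10     A
08      80     5      5      10     A
XX
//
ID  M_E2F_SYN
BF  E2F
DE  synthetic TTTCGCGC-like matrix
P0      A      C      G      T
01      5      10     5      80     T
02      5      10     5      80     T
03      5      10     5      80     T
04      5      80     5      10     C
05      5      5      80     10     G
06      5      80     5      10     C
07      5      5      80     10     G
08      5      80     5      10     C
XX
//
ID  M_PBX1_SYN
BF  PBX1
DE  synthetic TGATTGAT-like matrix
P0      A      C      G      T
01      5      5      10     80     T
02      10     5      80     5      G
03      80     5      5      10     A
04      5      5      10     80     T
05      5      5      10     80     T
06      10     5      80     5      G
07      80     5      5      10     A
08      5      5      10     80     T
XX
//
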