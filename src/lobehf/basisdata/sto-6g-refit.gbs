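! STO-6G-style p-shell reference data, re-derived (not copied from
! the Basis Set Exchange): six-Gaussian overlap-maximizing fits to
! Slater p orbitals at zeta=1, exponents scaled by the element zeta
! implied by the shipped STO-3G tabulation.  Used only as the
! fitting target for the displaced-lobe p representation.
****
C     0
P   6   1.00   ! 2p
          17.36066751    0.00792427
           4.52731584    0.05144124
           1.61991606    0.18984070
           0.67715610    0.40498657
           0.30964215    0.40123549
           0.14638797    0.10518514
****
N     0
P   6   1.00   ! 2p
          22.31406759    0.00792427
           5.81906379    0.05144124
           2.08211559    0.18984070
           0.87036441    0.40498657
           0.39799022    0.40123549
           0.18815585    0.10518514
****
O     0
P   6   1.00   ! 2p
          29.70807788    0.00792427
           7.74727420    0.05144124
           2.77204736    0.18984070
           1.15876917    0.40498657
           0.52986864    0.40123549
           0.25050335    0.10518514
****
P     0
P   6   1.00   ! 2p
         165.46211116    0.00792427
          43.14921855    0.05144124
          15.43919501    0.18984070
           6.45388078    0.40498657
           2.95115637    0.40123549
           1.39520346    0.10518514
P   6   1.00   ! 3p
          18.33129591   -0.00332997
           4.84022278   -0.01419486
           0.81168573    0.16393928
           0.40855917    0.44853555
           0.21935857    0.39088163
           0.11968692    0.07411483
****
S     0
P   6   1.00   ! 2p
         196.72821284    0.00792427
          51.30279429    0.05144124
          18.35662086    0.18984070
           7.67342096    0.40498657
           3.50881367    0.40123549
           1.65884432    0.10518514
P   6   1.00   ! 3p
          21.33996425   -0.00332997
           5.63463607   -0.01419486
           0.94490562    0.16393928
           0.47561493    0.44853555
           0.25536133    0.39088163
           0.13933083    0.07411483
****
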