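! STO-3G minimal basis, Gaussian94 dialect.
! Standard published tabulation (Hehre/Stewart/Pople scaled expansions).
! Shells appear in principal-quantum-number order: S, then SP groups.
****
H     0
S   3   1.00
      3.42525091         0.15432897
      0.62391373         0.53532814
      0.16885540         0.44463454
****
He     0
S   3   1.00
      6.36242139         0.15432897
      1.15892300         0.53532814
      0.31364979         0.44463454
****
C     0
S   3   1.00
     71.61683700         0.15432897
     13.04509600         0.53532814
      3.53051220         0.44463454
SP   3   1.00
      2.94124940        -0.09996723         0.15591627
      0.68348310         0.39951283         0.60768372
      0.22228990         0.70011547         0.39195739
****
N     0
S   3   1.00
     99.10616900         0.15432897
     18.05231200         0.53532814
      4.88566020         0.44463454
SP   3   1.00
      3.78045590        -0.09996723         0.15591627
      0.87849660         0.39951283         0.60768372
      0.28571440         0.70011547         0.39195739
****
O     0
S   3   1.00
    130.70932000         0.15432897
     23.80886100         0.53532814
      6.44360830         0.44463454
SP   3   1.00
      5.03315130        -0.09996723         0.15591627
      1.16959610         0.39951283         0.60768372
      0.38038900         0.70011547         0.39195739
****
P     0
S   3   1.00
    468.36563780         0.15432897
     85.31338559         0.53532814
     23.08913156         0.44463454
SP   3   1.00
     28.03263958        -0.09996723         0.15591627
      6.51418258         0.39951283         0.60768372
      2.11861435         0.70011547         0.39195739
SP   3   1.00
      1.74310323        -0.21962037         0.01058760
      0.48632062         0.22559543         0.59516701
      0.19034290         0.90039843         0.46200101
****
S     0
S   3   1.00
    533.12573590         0.15432897
     97.10951830         0.53532814
     26.28162542         0.44463454
SP   3   1.00
     33.32975173        -0.09996723         0.15591627
      7.74511752         0.39951283         0.60768372
      2.51895260         0.70011547         0.39195739
SP   3   1.00
      2.02919427        -0.21962037         0.01058760
      0.56614005         0.22559543         0.59516701
      0.22158338         0.90039843         0.46200101
****
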